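"""Shared data containers and readers/writers for the standard on-disk formats.

The pipeline works with three kinds of artifact:

* sparse single-cell count matrices in MatrixMarket (MTX) coordinate form with
  TSV sidecars listing gene and cell identifiers (the 10x-style triplet layout);
* gene-set collections in GMT, optionally with a companion two-column mapping
  that tags each set as belonging to the telomerase (TEL) group, the
  alternative-lengthening (ALT) group, or neither;
* flat TSV tables for every derived per-cell / per-gene result.

Gene identity is by symbol string, case-sensitive; no alias resolution is
attempted. All readers handle ``.gz`` paths transparently.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "FormatError",
    "read_mtx",
    "write_mtx",
    "read_gmt",
    "write_gmt",
    "read_group_map",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """A file violates the structural contract of its format."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Cells x genes non-negative integer count matrix with identifiers.

    ``values`` is kept as CSR sparse; ``gene_ids`` and ``cell_ids`` are ordered
    and duplicate-free, with lengths matching the matrix dimensions.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        self.values = self.values.tocsr()
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_cells, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("duplicate cell ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts")
        data = self.values.data
        if data.size and not np.allclose(data, np.round(data)):
            raise ValueError("non-integer counts")
        self.values.data = np.asarray(np.round(self.values.data), dtype=np.int64)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_cells(self, keep: Iterable[str]) -> "CountMatrix":
        keep = list(keep)
        index = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in keep if c not in index]
        if missing:
            raise ValueError(f"unknown cell ids: {missing[:5]}")
        rows = [index[c] for c in keep]
        return CountMatrix(self.values[rows], list(self.gene_ids), keep)


@dataclass
class GeneSetCollection:
    """Named gene sets, each tagged with a TMM group (TEL / ALT / other)."""

    sets: dict[str, list[str]]
    group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.group.setdefault(name, "other")
        bad = {g for g in self.group.values()} - {"TEL", "ALT", "other"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return list(self.sets[name])

    def names_in_group(self, group: str) -> list[str]:
        return [n for n in self.sets if self.group.get(n) == group]

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        names = list(names)
        return GeneSetCollection(
            {n: list(self.sets[n]) for n in names},
            {n: self.group.get(n, "other") for n in names},
        )


# ---------------------------------------------------------------------------
# MatrixMarket + sidecars
# ---------------------------------------------------------------------------

def read_mtx(
    matrix_path,
    genes_path,
    cells_path,
    orientation: str = "genes-by-cells",
) -> CountMatrix:
    """Read a 10x-style MTX triplet with gene/cell TSV sidecars.

    ``orientation`` declares the on-disk layout: ``"genes-by-cells"`` (the 10x
    convention, default) or ``"cells-by-genes"``. The returned matrix is always
    cells x genes.
    """
    if orientation not in ("genes-by-cells", "cells-by-genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with _open_text(matrix_path, "rb") as fh:
        try:
            mat = scipy.io.mmread(io.BytesIO(fh.read()))
        except ValueError as exc:
            raise FormatError(f"bad MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError(f"non-integer entries in {matrix_path}")
    if mat.data.size and mat.data.min() < 0:
        raise ValueError(f"negative entries in {matrix_path}")

    genes = _read_id_column(genes_path)
    cells = _read_id_column(cells_path)
    if orientation == "genes-by-cells":
        n_genes, n_cells = mat.shape
        mat = mat.T
    else:
        n_cells, n_genes = mat.shape
    if len(genes) != n_genes:
        raise FormatError(
            f"{len(genes)} genes in sidecar but matrix has {n_genes}"
        )
    if len(cells) != n_cells:
        raise FormatError(
            f"{len(cells)} cells in sidecar but matrix has {n_cells}"
        )
    return CountMatrix(sp.csr_matrix(mat), genes, cells)


def _read_id_column(path) -> list[str]:
    with _open_text(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return ids


def write_mtx(counts: CountMatrix, matrix_path, genes_path, cells_path,
              orientation: str = "genes-by-cells") -> None:
    """Write a CountMatrix back to MTX + sidecars (inverse of :func:`read_mtx`)."""
    mat = counts.values.tocoo()
    if orientation == "genes-by-cells":
        mat = mat.T
    elif orientation != "cells-by-genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    scipy.io.mmwrite(str(matrix_path), mat, field="integer")
    Path(genes_path).write_text("".join(g + "\n" for g in counts.gene_ids))
    Path(cells_path).write_text("".join(c + "\n" for c in counts.cell_ids))


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path, group_map: Mapping[str, str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (``name<TAB>description<TAB>gene...`` per line).

    Duplicate genes within a set are dropped, keeping first occurrence.
    ``group_map`` optionally assigns TEL/ALT group tags by set name; unmapped
    sets default to ``"other"``.
    """
    sets: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields (<3)"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    group = dict(group_map) if group_map else {}
    return GeneSetCollection(sets, {n: group.get(n, "other") for n in sets})


def write_gmt(sets: GeneSetCollection, path, description: str = "na") -> None:
    with _open_text(path, "wt") as fh:
        for name, genes in sets.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_group_map(path) -> dict[str, str]:
    """Read a two-column TSV mapping set name -> group (TEL / ALT / other)."""
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"group map line needs 2 fields: {line!r}")
            mapping[fields[0]] = fields[1]
    return mapping


# ---------------------------------------------------------------------------
# tabular artifacts
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path) -> None:
    """Write a table as TSV, round-trippable at 12 significant digits."""
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
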