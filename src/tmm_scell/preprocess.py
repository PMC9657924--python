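"""Per-cell QC metrics, cell filtering and library-size log-normalization.

The QC rule keeps cells with at least ``min_features`` detected genes and a
mitochondrial count percentage on the right side of ``mito_pct_threshold``.
High mitochondrial content usually marks damaged or dying cells, so the
conventional direction — and the default here — is ``keep_below``: retain
cells *under* the threshold. The opposite reading (``keep_above``) is exposed
for completeness via ``mito_rule``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import CountMatrix

__all__ = ["QCThresholds", "compute_qc", "filter_cells", "lognormalize"]


@dataclass
class QCThresholds:
    min_features: int = 200
    mito_pct_threshold: float = 5.0
    mito_rule: str = "keep_below"

    def __post_init__(self) -> None:
        if self.min_features < 0:
            raise ValueError("min_features must be >= 0")
        if not 0 <= self.mito_pct_threshold <= 100:
            raise ValueError("mito_pct_threshold must lie in [0, 100]")
        if self.mito_rule not in ("keep_below", "keep_above"):
            raise ValueError("mito_rule must be keep_below or keep_above")


def compute_qc(counts: CountMatrix, mito_genes: list[str]) -> pd.DataFrame:
    """Per-cell QC table: n_features, total_counts, pct_mito, zero_total flag.

    ``pct_mito`` is 100 * (mito counts) / (total counts), with the total over
    all genes; all-zero cells get pct_mito 0 and ``zero_total`` True.
    """
    x = counts.values
    n_features = np.asarray((x > 0).sum(axis=1)).ravel()
    total = np.asarray(x.sum(axis=1)).ravel()

    gene_index = {g: i for i, g in enumerate(counts.gene_ids)}
    present = [g for g in mito_genes if g in gene_index]
    missing = [g for g in mito_genes if g not in gene_index]
    if missing:
        warnings.warn(
            f"{len(missing)} mito genes absent from matrix: {missing[:5]}"
        )
    if not present:
        if mito_genes is not None and len(mito_genes) == 0:
            warnings.warn("empty mito gene list; pct_mito will be 0 for all cells")
        mito_counts = np.zeros(counts.n_cells)
    else:
        cols = [gene_index[g] for g in present]
        mito_counts = np.asarray(x[:, cols].sum(axis=1)).ravel()

    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito_counts / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "n_features": n_features.astype(int),
            "total_counts": total.astype(int),
            "pct_mito": pct,
            "zero_total": total == 0,
        }
    )


def filter_cells(qc: pd.DataFrame, thr: QCThresholds | None = None) -> list[str]:
    """Cell ids passing the QC rule, in input order."""
    thr = thr or QCThresholds()
    ok_features = qc["n_features"] >= thr.min_features
    if thr.mito_rule == "keep_below":
        ok_mito = qc["pct_mito"] < thr.mito_pct_threshold
    else:
        ok_mito = qc["pct_mito"] > thr.mito_pct_threshold
    return list(qc.loc[ok_features & ok_mito, "cell_id"])


def lognormalize(counts: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """Library-size normalize then log-transform: x -> ln(1 + scale*x/total).

    Zeros map to zeros exactly; the result is invariant to scaling any cell's
    counts by a positive constant. Returns a dense cells x genes array.
    """
    total = np.asarray(counts.values.sum(axis=1)).ravel().astype(float)
    if (total == 0).any():
        bad = int((total == 0).sum())
        raise ValueError(
            f"{bad} all-zero cells; run filter_cells before normalizing"
        )
    x = counts.values.tocsr().astype(float)
    x = sp.diags(scale / total) @ x
    x.data = np.log1p(x.data)
    return np.asarray(x.todense())
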