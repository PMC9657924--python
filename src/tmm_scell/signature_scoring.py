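"""Per-cell single-sample gene-set enrichment (ssGSEA) scoring.

For one cell, genes are ranked by expression (1 = lowest, N = highest; ties
broken deterministically by gene identifier) and the enrichment score of a
gene set G walks the genes in decreasing rank order, accumulating the gap
between a rank-weighted in-set ECDF and the uniform out-of-set ECDF:

    P_in(i)  = sum_{g in G, pos(g) <= i} r_g**alpha / sum_{g in G} r_g**alpha
    P_out(i) = #{g not in G, pos(g) <= i} / (N - |G|)
    ES       = sum_i [P_in(i) - P_out(i)]

Because each gene at rank r contributes to the running sums at exactly the r
highest positions, the double loop collapses to a closed form over set
members only:

    ES = sum_{g in G} r_g**(alpha+1) / sum_{g in G} r_g**alpha
         - (T - sum_{g in G} r_g) / (N - |G|),      T = N(N+1)/2

which this module uses; the naive running sum serves as a cross-check in the
test suite. Scores depend on expression only through ranks, so they are
invariant to any strictly increasing per-cell transform. With
``normalize=True`` (the ssGSEA convention) all raw scores are divided by the
max-minus-min over the whole score matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneSetCollection

__all__ = ["ScoringParams", "rank_cell", "rank_matrix", "ssgsea_es",
           "es_closed_form", "score_matrix", "ScoreResult"]


@dataclass
class ScoringParams:
    alpha: float = 0.25
    normalize: bool = True
    min_set_overlap: int = 3

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.min_set_overlap < 1:
            raise ValueError("min_set_overlap must be >= 1")


def rank_cell(expression: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """Ranks 1..N, highest expression -> N; ties by ascending gene id."""
    expression = np.asarray(expression, dtype=float)
    n = expression.size
    if n < 2:
        raise ValueError("need at least 2 genes to rank")
    tie_key = np.argsort(np.argsort(np.asarray(gene_ids)))
    order = np.lexsort((tie_key, expression))  # ascending expr, ties by gene id
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def rank_matrix(matrix: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """Row-wise :func:`rank_cell` for a cells x genes matrix."""
    matrix = np.asarray(matrix, dtype=float)
    n_cells, n_genes = matrix.shape
    tie_key = np.argsort(np.argsort(np.asarray(gene_ids)))
    ranks = np.empty_like(matrix, dtype=np.int64)
    cols = np.arange(1, n_genes + 1)
    for i in range(n_cells):
        order = np.lexsort((tie_key, matrix[i]))
        ranks[i, order] = cols
    return ranks


def es_closed_form(ranks: np.ndarray, member_idx: np.ndarray, alpha: float) -> float:
    """Enrichment score from per-gene ranks and in-set column indices."""
    ranks = np.asarray(ranks, dtype=float)
    n = ranks.size
    m = member_idx.size
    if not 1 <= m < n:
        raise ValueError("need 1 <= |G| < N")
    r = ranks[member_idx]
    w = r ** alpha
    total = n * (n + 1) / 2.0
    return float((w * r).sum() / w.sum() - (total - r.sum()) / (n - m))


def ssgsea_es(
    ranks: np.ndarray,
    gene_set: list[str],
    gene_ids: list[str],
    alpha: float = 0.25,
) -> float:
    """Enrichment score of ``gene_set`` against one cell's ranks.

    Genes of the set absent from ``gene_ids`` are ignored; at least one must
    be present and the set must not cover the whole universe.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    members = np.array([index[g] for g in gene_set if g in index], dtype=int)
    if members.size == len(gene_ids):
        raise ValueError("gene set covers the whole universe; P_out undefined")
    if members.size == 0:
        raise ValueError("gene set has no overlap with the universe")
    return es_closed_form(np.asarray(ranks), members, alpha)


@dataclass
class ScoreResult:
    """Cells x sets score table plus bookkeeping.

    ``scores``: DataFrame indexed by cell id, one column per scored set.
    ``raw``: same shape, pre-normalization enrichment scores.
    ``effective_size``: per-set gene count after intersection with the matrix.
    ``skipped``: sets dropped for insufficient overlap.
    """

    scores: pd.DataFrame
    raw: pd.DataFrame
    effective_size: dict[str, int]
    skipped: list[str]
    normalized: bool


def score_matrix(
    matrix: np.ndarray,
    gene_ids: list[str],
    cell_ids: list[str],
    sets: GeneSetCollection,
    params: ScoringParams | None = None,
) -> ScoreResult:
    """ssGSEA scores for every (cell, set) pair.

    Sets overlapping the gene universe in fewer than ``min_set_overlap``
    genes are skipped with a warning. With ``normalize=True``, scores are
    divided by (max - min) over the whole raw matrix.
    """
    params = params or ScoringParams()
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] != len(gene_ids):
        raise ValueError("matrix width does not match gene_ids")
    index = {g: i for i, g in enumerate(gene_ids)}

    member_cols: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for name in sets.names():
        cols = np.array([index[g] for g in sets.members(name) if g in index], int)
        if cols.size < params.min_set_overlap or cols.size >= len(gene_ids):
            skipped.append(name)
            continue
        member_cols[name] = cols
    if skipped:
        warnings.warn(f"skipping {len(skipped)} sets with overlap < "
                      f"{params.min_set_overlap}: {skipped[:5]}")
    if not member_cols:
        raise ValueError("no gene set has sufficient overlap with the matrix")

    ranks = rank_matrix(matrix, gene_ids).astype(float)
    n = len(gene_ids)
    total = n * (n + 1) / 2.0
    w = ranks ** params.alpha
    wr = w * ranks

    raw = np.empty((matrix.shape[0], len(member_cols)))
    for j, (name, cols) in enumerate(member_cols.items()):
        m = cols.size
        raw[:, j] = (wr[:, cols].sum(axis=1) / w[:, cols].sum(axis=1)
                     - (total - ranks[:, cols].sum(axis=1)) / (n - m))

    raw_df = pd.DataFrame(raw, index=list(cell_ids), columns=list(member_cols))
    raw_df.index.name = "cell_id"
    if params.normalize:
        span = raw.max() - raw.min()
        scores_df = raw_df / span if span > 0 else raw_df.copy()
    else:
        scores_df = raw_df.copy()
    return ScoreResult(
        scores=scores_df,
        raw=raw_df,
        effective_size={n_: c.size for n_, c in member_cols.items()},
        skipped=skipped,
        normalized=params.normalize,
    )
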