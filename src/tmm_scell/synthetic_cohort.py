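"""Synthetic single-cell cohorts with planted TMM signature activity.

Real TMM typing was done on gastric-cancer cohorts that cannot be bundled
here, so this module generates cohorts carrying the statistical structure the
classifier assumes: negative-binomial counts with gene-specific means,
logistic mean-dependent dropout, several cell types, a designated
mitochondrial gene block with a controlled per-cell count share, and per-cell
TMM states that up-regulate the corresponding signature gene sets.

Each cell is independently assigned one of the four TMM states:

* ``TEL`` cells activate every TEL-group signature set,
* ``ALT-like`` cells activate every ALT-group set,
* ``TEL+ALT-like`` cells activate both groups,
* ``NDTMM`` cells activate nothing.

"Activating" a set multiplies the NB mean of its member genes in that cell by
``2**signature_lfc``. TMM state is planted per cell, not per cell type, so
within-cell-type TMM heterogeneity is present by construction. Everything is
reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import CountMatrix, GeneSetCollection

__all__ = [
    "SimConfig",
    "TMM_LABELS",
    "simulate_cohort",
    "simulate_null_cohort",
    "demo_tmm_collection",
    "simulated_universe",
]

TMM_LABELS = ("TEL", "ALT-like", "TEL+ALT-like", "NDTMM")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe a modest desk-scale tumor cohort: 1000 cells, 2000
    genes, four equally frequent cell types and TMM states, gene means
    log-normal around 1 count, NB size 2 (overdispersed), logistic dropout
    centred at mean 1, and 1-10% mitochondrial content.
    """

    n_cells: int = 1000
    n_genes: int = 2000
    cell_type_props: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    tmm_props: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    baseline_log_mean: float = 0.0
    gene_mean_sd: float = 1.0
    nb_dispersion: float = 2.0
    dropout_midpoint: float = 0.0
    dropout_slope: float = 1.0
    signature_lfc: float = 1.0
    mito_fraction_range: tuple[float, float] = (0.01, 0.10)
    n_mito_genes: int = 10
    cell_type_lfc: float = 1.0
    genes_per_cell_type: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for name in ("cell_type_props", "tmm_props"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.size == 0 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("mito_fraction_range must satisfy 0 <= lo <= hi <= 1")
        if len(self.tmm_props) != 4:
            raise ValueError("tmm_props must have 4 entries (TEL, ALT-like, "
                             "TEL+ALT-like, NDTMM)")


def simulated_universe(n_genes: int, n_mito_genes: int = 10) -> list[str]:
    """Gene ids ``G0000...`` plus a trailing mito block ``MT-0 ...``."""
    n_reg = n_genes - n_mito_genes
    if n_reg < 1:
        raise ValueError("n_mito_genes must leave at least one regular gene")
    return [f"G{i:04d}" for i in range(n_reg)] + \
        [f"MT-{i}" for i in range(n_mito_genes)]


def demo_tmm_collection(
    n_genes: int = 2000,
    sets_per_group: int = 3,
    genes_per_set: int = 20,
    n_mito_genes: int = 10,
    seed: int = 20221023,
) -> GeneSetCollection:
    """Six-pathway demo TMM signature over the synthetic gene universe.

    The published TMM signature gene lists are not reproduced here; this
    builds a stand-in with the same shape — ``sets_per_group`` telomerase
    (TEL) pathways and as many ALT pathways, disjoint, with member genes
    drawn at random (fixed seed) from the non-mitochondrial part of
    :func:`simulated_universe`, as real signature genes are scattered across
    the transcriptome rather than clustered.
    """
    need = 2 * sets_per_group * genes_per_set
    universe = simulated_universe(n_genes, n_mito_genes)[: n_genes - n_mito_genes]
    if need > len(universe):
        raise ValueError("gene universe too small for requested signature")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(universe), size=need, replace=False)
    sets: dict[str, list[str]] = {}
    group: dict[str, str] = {}
    pos = 0
    for grp, tag in (("TEL", "TEL"), ("ALT", "ALT")):
        for j in range(sets_per_group):
            name = f"{grp}_PATHWAY_{j + 1}"
            idx = chosen[pos:pos + genes_per_set]
            sets[name] = [universe[i] for i in idx]
            group[name] = tag
            pos += genes_per_set
    return GeneSetCollection(sets, group)


def _gene_universe(config: SimConfig) -> tuple[list[str], np.ndarray]:
    genes = simulated_universe(config.n_genes, config.n_mito_genes)
    mito_mask = np.zeros(config.n_genes, dtype=bool)
    mito_mask[config.n_genes - config.n_mito_genes:] = True
    return genes, mito_mask


_ACTIVE_GROUPS = {
    "TEL": ("TEL",),
    "ALT-like": ("ALT",),
    "TEL+ALT-like": ("TEL", "ALT"),
    "NDTMM": (),
}


def simulate_cohort(
    config: SimConfig, sets: GeneSetCollection | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a cohort and its ground truth.

    Returns ``(counts, truth)`` where ``truth`` has one row per cell with
    columns ``cell_id``, ``cell_type``, ``tmm_type``, ``planted_active_sets``
    (comma-joined set names) and ``mito_fraction`` (the planted share).
    """
    if sets is None:
        sets = demo_tmm_collection(config.n_genes)
    rng = np.random.default_rng(config.seed)
    genes, mito_mask = _gene_universe(config)
    gene_index = {g: i for i, g in enumerate(genes)}

    tmm_set_names = sets.names_in_group("TEL") + sets.names_in_group("ALT")
    for name in tmm_set_names:
        missing = [g for g in sets.members(name) if g not in gene_index]
        if missing:
            raise ValueError(
                f"signature genes absent from universe in {name!r}: {missing[:5]}"
            )

    n_cells, n_genes = config.n_cells, config.n_genes
    n_reg = n_genes - config.n_mito_genes

    # per-gene baseline mean (log-normal)
    log_mu = rng.normal(config.baseline_log_mean, config.gene_mean_sd, size=n_genes)
    base_mu = np.exp(log_mu)

    # cell identity draws
    cell_types = rng.choice(
        len(config.cell_type_props), size=n_cells, p=np.asarray(config.cell_type_props, float)
    )
    tmm_states = rng.choice(4, size=n_cells, p=np.asarray(config.tmm_props, float))
    mito_frac = rng.uniform(*config.mito_fraction_range, size=n_cells)

    # cell-type marker blocks: each type up-regulates its own slice of regular
    # genes (disjoint from the signature genes) so cell types are separable
    sig_idx = {gene_index[g] for n_ in tmm_set_names for g in sets.members(n_)}
    candidates = [i for i in range(n_reg) if i not in sig_idx]
    n_marker = len(config.cell_type_props) * config.genes_per_cell_type
    if n_marker > len(candidates):
        raise ValueError("not enough regular genes for cell-type marker blocks")
    marker_idx = np.array(candidates[-n_marker:])

    # per-cell mean matrix
    mu = np.tile(base_mu, (n_cells, 1))
    for t in range(len(config.cell_type_props)):
        block = marker_idx[t * config.genes_per_cell_type:
                           (t + 1) * config.genes_per_cell_type]
        mu[np.ix_(cell_types == t, block)] *= 2.0 ** config.cell_type_lfc

    set_cols = {
        name: np.array([gene_index[g] for g in sets.members(name)])
        for name in tmm_set_names
    }
    planted: list[list[str]] = [[] for _ in range(n_cells)]
    factor = 2.0 ** config.signature_lfc
    for state_idx, label in enumerate(TMM_LABELS):
        rows = np.flatnonzero(tmm_states == state_idx)
        if rows.size == 0:
            continue
        for grp in _ACTIVE_GROUPS[label]:
            for name in sets.names_in_group(grp):
                mu[np.ix_(rows, set_cols[name])] *= factor
                for r in rows:
                    planted[r].append(name)

    # NB draws: size (dispersion) theta, p = theta / (theta + mu)
    theta = config.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))

    # logistic dropout on the (cell, gene) mean; midpoint of -inf disables
    # dropout entirely (the zero-dropout limit for any slope)
    if np.isneginf(config.dropout_midpoint):
        p_drop = np.zeros_like(mu)
    else:
        logit = config.dropout_slope * (config.dropout_midpoint - np.log(mu))
        p_drop = 1.0 / (1.0 + np.exp(-logit))
    counts = np.where(rng.random(mu.shape) < p_drop, 0, counts)

    # mito block: give each cell a mito count share ~= its planted fraction
    mito_p = base_mu[mito_mask] / base_mu[mito_mask].sum()
    nonmito_tot = counts[:, :n_reg].sum(axis=1)
    mito_tot = np.round(mito_frac / (1.0 - mito_frac) * nonmito_tot).astype(int)
    counts[:, n_reg:] = rng.multinomial(mito_tot, mito_p)

    truth = pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(n_cells)],
            "cell_type": [f"type{t}" for t in cell_types],
            "tmm_type": [TMM_LABELS[s] for s in tmm_states],
            "planted_active_sets": [",".join(p) for p in planted],
            "mito_fraction": mito_frac,
        }
    )
    matrix = CountMatrix(sp.csr_matrix(counts), genes, list(truth["cell_id"]))
    return matrix, truth


def simulate_null_cohort(
    config: SimConfig, sets: GeneSetCollection | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Cohort with no planted signature signal; every cell is NDTMM."""
    null_cfg = replace(config, signature_lfc=0.0, tmm_props=(0.0, 0.0, 0.0, 1.0))
    return simulate_cohort(null_cfg, sets)
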