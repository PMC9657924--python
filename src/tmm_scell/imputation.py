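"""Markov-diffusion (MAGIC-style) imputation of normalized expression.

Dropout leaves the observed expression matrix sparse and noisy; diffusion
imputation denoises it by averaging each cell with its transcriptional
neighborhood. The operator is built in three steps:

1. Euclidean distances between cells in the top ``n_pcs`` principal
   components of the normalized matrix;
2. an adaptive Gaussian kernel ``A_ij = exp(-(d_ij / sigma_i)**2)`` with
   ``sigma_i`` the distance from cell ``i`` to its ``ka``-th nearest
   neighbor, truncated to zero beyond the ``k``-th neighbor;
3. symmetrization ``A <- (A + A.T) / 2`` followed by row normalization,
   giving a row-stochastic Markov matrix ``M``.

Imputation is then ``t`` steps of diffusion, ``M^t @ X``, applied by repeated
left-multiplication. ``t=0`` returns the input unchanged. Diffusion can only
average: each imputed value stays within the observed range of its gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

__all__ = ["DiffusionParams", "build_markov", "diffuse", "impute"]


@dataclass
class DiffusionParams:
    k: int = 15
    ka: int = 5
    t: int = 3
    n_pcs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.ka <= self.k:
            raise ValueError("need 1 <= ka <= k")
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")


def _pc_scores(x: np.ndarray, n_pcs: int, seed: int) -> np.ndarray:
    n_pcs = min(n_pcs, min(x.shape) - 1)
    if n_pcs < 1:
        return x - x.mean(axis=0)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    return pca.fit_transform(x)


def build_markov(norm_matrix: np.ndarray, params: DiffusionParams | None = None) -> np.ndarray:
    """Row-stochastic cell-cell Markov operator from an adaptive kernel."""
    params = params or DiffusionParams()
    x = np.asarray(norm_matrix, dtype=float)
    n_cells = x.shape[0]
    if params.k >= n_cells:
        raise ValueError(f"k={params.k} needs at least k+1={params.k + 1} cells")

    pcs = _pc_scores(x, params.n_pcs, params.seed)
    dist = cdist(pcs, pcs)
    ordered = np.sort(dist, axis=1)  # column 0 is the cell itself (d = 0)

    sigma = ordered[:, params.ka].copy()  # distance to ka-th neighbor
    # distances are computed in PC space, where exact duplicates pick up
    # ~1e-16 float jitter; treat bandwidths below a relative tolerance as zero
    tol = 1e-12 * max(float(dist.max()), 1.0)
    zero_sigma = sigma <= tol
    if zero_sigma.any():
        warnings.warn(
            f"{int(zero_sigma.sum())} cells with zero kernel bandwidth "
            "(duplicate cells); substituting smallest positive neighbor distance"
        )
        for i in np.flatnonzero(zero_sigma):
            pos = dist[i][dist[i] > tol]
            sigma[i] = pos.min() if pos.size else 1.0

    # truncate beyond the k-th neighbor; the radius is tie-aware so exactly
    # coincident cells are treated symmetrically
    radius = ordered[:, params.k]
    keep = dist <= radius[:, None] + tol
    affinity = np.where(keep, np.exp(-((dist / sigma[:, None]) ** 2)), 0.0)

    affinity = (affinity + affinity.T) / 2.0
    markov = affinity / affinity.sum(axis=1, keepdims=True)
    return markov


def diffuse(norm_matrix: np.ndarray, markov: np.ndarray, t: int) -> np.ndarray:
    """Apply ``t`` diffusion steps, returning ``M^t @ X`` without forming M^t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    x = np.asarray(norm_matrix, dtype=float)
    row_sums = markov.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-9):
        raise ValueError("markov matrix rows must sum to 1")
    for _ in range(t):
        x = markov @ x
    return x


def impute(norm_matrix: np.ndarray, params: DiffusionParams | None = None) -> np.ndarray:
    """Convenience composition: build the operator, then diffuse ``params.t`` steps."""
    params = params or DiffusionParams()
    markov = build_markov(norm_matrix, params)
    return diffuse(norm_matrix, markov, params.t)
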