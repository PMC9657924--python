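"""Downstream characterization of TMM types.

Four families of analysis follow the per-cell TMM call:

* **transcriptome entropy** — Shannon entropy of each cell's normalized
  expression distribution, the standard proxy for stemness/potency: a cell
  spreading its transcriptional output over many genes (high entropy) is less
  committed than one dominated by few transcripts;
* **clustering** — PCA + k-means cell clusters, used to compare entropy and
  TMM composition across transcriptional neighborhoods;
* **marker summaries** — per-TMM-type expression summaries of marker genes
  (e.g. the proliferation marker MKI67, or PML as a telomere-length proxy)
  with rank-sum tests of each type against the rest;
* **zero-inflated negative binomial (ZINB) differential expression** — a
  two-part model per gene, ``P(x=0) = pi + (1-pi) NB(0; mu, theta)`` and
  ``P(x=k>0) = (1-pi) NB(k; mu, theta)``, compared between two cell groups by
  likelihood-ratio tests. Genes can differ in their zero fraction only
  ("status", DEs), in the non-zero abundance only (DEa), or in both (DEg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .tmm_classification import bh_fdr

__all__ = [
    "ClusterParams",
    "cell_entropy",
    "cluster_cells",
    "entropy_by_cluster",
    "marker_summary",
    "ZINBFit",
    "zinb_fit",
    "de_two_group",
]


# ---------------------------------------------------------------------------
# entropy & clustering
# ---------------------------------------------------------------------------

def cell_entropy(norm_matrix: np.ndarray) -> np.ndarray:
    """Shannon entropy (natural log) of each cell's expression distribution.

    Each row is renormalized to a probability vector; ``0 * ln 0`` counts as
    zero. Bounds: 0 (one-hot cell) to ln(N) (uniform cell).
    """
    x = np.asarray(norm_matrix, dtype=float)
    totals = x.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every cell needs positive total expression")
    p = x / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1)


@dataclass
class ClusterParams:
    n_clusters: int = 10
    n_pcs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")


def cluster_cells(matrix: np.ndarray, params: ClusterParams) -> np.ndarray:
    """k-means labels (1..n_clusters) on the top principal components."""
    x = np.asarray(matrix, dtype=float)
    if params.n_clusters >= x.shape[0]:
        raise ValueError("n_clusters must be < n_cells")
    n_pcs = min(params.n_pcs, min(x.shape) - 1)
    pcs = PCA(n_components=n_pcs, svd_solver="full",
              random_state=params.seed).fit_transform(x)
    km = KMeans(n_clusters=params.n_clusters, n_init=10,
                random_state=params.seed)
    return km.fit_predict(pcs) + 1


def entropy_by_cluster(
    entropy: np.ndarray,
    labels: np.ndarray,
    calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cluster entropy summary and TMM composition.

    One row per cluster with mean/median entropy, a rank-sum p (cluster vs
    all other cells) BH-corrected across clusters, and — when ``calls`` is
    given, aligned positionally — the percentage of each TMM label.
    """
    entropy = np.asarray(entropy, float)
    labels = np.asarray(labels)
    if entropy.size != labels.size:
        raise ValueError("entropy and cluster labels differ in length")
    if calls is not None and len(calls) != entropy.size:
        raise ValueError("calls not aligned with entropy/labels")
    rows = []
    uniq = sorted(pd.unique(labels))
    pvals = []
    for lab in uniq:
        mask = labels == lab
        if mask.all() or not mask.any():
            pvals.append(1.0)
        else:
            pvals.append(scipy.stats.ranksums(entropy[mask], entropy[~mask]).pvalue)
    qvals = bh_fdr(np.asarray(pvals))
    for lab, p, q in zip(uniq, pvals, qvals):
        mask = labels == lab
        row = {
            "cluster": lab,
            "n_cells": int(mask.sum()),
            "mean_entropy": float(entropy[mask].mean()),
            "median_entropy": float(np.median(entropy[mask])),
            "p_vs_rest": float(p),
            "q_vs_rest": float(q),
        }
        if calls is not None:
            sub = calls.iloc[np.flatnonzero(mask)]
            for tmm in ("TEL", "ALT-like", "TEL+ALT-like", "NDTMM"):
                row[f"pct_{tmm}"] = 100.0 * float((sub["label"] == tmm).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def marker_summary(
    matrix: np.ndarray,
    gene_ids: list[str],
    markers: list[str],
    calls: pd.DataFrame,
    min_group: int = 3,
) -> pd.DataFrame:
    """Mean/median marker expression per TMM label with rank-sum tests.

    Each (label, marker) pair is tested against cells of all other labels;
    p-values are BH-corrected over all pairs. Groups smaller than
    ``min_group`` get NA p-values. Markers missing from the matrix are
    dropped with a warning; at least one must be present.
    """
    import warnings

    index = {g: i for i, g in enumerate(gene_ids)}
    present = [m for m in markers if m in index]
    missing = [m for m in markers if m not in index]
    if missing:
        warnings.warn(f"markers absent from matrix: {missing}")
    if not present:
        raise ValueError("no requested marker found in the matrix")
    x = np.asarray(matrix, float)
    labels = calls["label"].to_numpy()
    rows = []
    for marker in present:
        col = x[:, index[marker]]
        for lab in sorted(pd.unique(labels)):
            mask = labels == lab
            vals, rest = col[mask], col[~mask]
            if mask.sum() >= min_group and (~mask).sum() >= min_group:
                p = float(scipy.stats.ranksums(vals, rest).pvalue)
            else:
                p = np.nan
            rows.append({
                "marker": marker,
                "tmm_type": lab,
                "n_cells": int(mask.sum()),
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "p_vs_rest": p,
            })
    out = pd.DataFrame(rows)
    tested = out["p_vs_rest"].notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_fdr(out.loc[tested, "p_vs_rest"].to_numpy())
    out["q_vs_rest"] = q
    return out


# ---------------------------------------------------------------------------
# zero-inflated negative binomial
# ---------------------------------------------------------------------------

_PI_MAX = 1.0 - 1e-6
_EPS = 1e-8


def _aggregate(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique values and multiplicities (likelihood is a weighted sum)."""
    vals, counts = np.unique(x, return_counts=True)
    return vals.astype(float), counts.astype(float)


def _nb_logpmf(vals: np.ndarray, mu: float, theta: float) -> np.ndarray:
    return scipy.stats.nbinom.logpmf(vals, theta, theta / (theta + mu))


def _zinb_nll_terms(vals, wts, pi, mu, theta):
    """Weighted negative log-likelihood of one ZINB component."""
    logpmf = _nb_logpmf(vals, mu, theta)
    zero = vals == 0
    ll = np.where(
        zero,
        np.log(pi + (1 - pi) * np.exp(logpmf) + 1e-300),
        np.log1p(-pi) + logpmf,
    )
    return -(wts * ll).sum()


@dataclass
class ZINBFit:
    pi: float
    mu: float
    theta: float
    loglik: float
    boundary: bool = False

    def astuple(self) -> tuple[float, float, float]:
        return (self.pi, self.mu, self.theta)


def _moment_init(x: np.ndarray) -> tuple[float, float, float]:
    """Deterministic starting point: moment estimates + excess-zero pi."""
    m = max(x.mean(), _EPS)
    v = x.var()
    theta0 = m * m / (v - m) if v > m else 10.0
    theta0 = float(np.clip(theta0, 0.01, 1e4))
    nb_zero = float(np.exp(_nb_logpmf(np.zeros(1), m, theta0)[0]))
    zero_frac = float((x == 0).mean())
    if nb_zero < 1.0:
        pi0 = max(0.0, (zero_frac - nb_zero) / (1.0 - nb_zero))
    else:
        pi0 = 0.0
    pos = x[x > 0]
    mu0 = float(pos.mean()) if pos.size else m
    return (min(pi0, _PI_MAX), max(mu0, _EPS), theta0)


def zinb_fit(x: np.ndarray) -> ZINBFit:
    """Maximum-likelihood ZINB fit of one gene's counts.

    Deterministic initialization (excess-zero pi, positive-part mean,
    method-of-moments theta), then bounded L-BFGS-B; the optimizer never
    reports a likelihood below the starting point. All-zero input returns
    the pi=1 boundary with ``mu``/``theta`` NaN and ``boundary=True``.
    """
    x = np.asarray(x)
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if (x < 0).any() or not np.allclose(x, np.round(x)):
        raise ValueError("counts must be non-negative integers")
    x = np.round(x).astype(int)
    if (x == 0).all():
        return ZINBFit(pi=1.0, mu=np.nan, theta=np.nan, loglik=0.0, boundary=True)

    vals, wts = _aggregate(x)
    p0 = _moment_init(x)

    def nll(params):
        pi, mu, theta = params
        return _zinb_nll_terms(vals, wts, pi, mu, theta)

    res = scipy.optimize.minimize(
        nll, p0, method="L-BFGS-B",
        bounds=[(0.0, _PI_MAX), (_EPS, None), (1e-4, 1e6)],
    )
    best = res.x if res.fun <= nll(p0) else np.asarray(p0)
    return ZINBFit(
        pi=float(best[0]), mu=float(best[1]), theta=float(best[2]),
        loglik=-float(min(res.fun, nll(p0))),
    )


# -- two-group fits with shared dispersion ----------------------------------

def _fit_bounded(nll, p0, bounds):
    res = scipy.optimize.minimize(nll, p0, method="L-BFGS-B", bounds=bounds)
    f0 = nll(np.asarray(p0))
    if res.fun <= f0:
        return np.asarray(res.x), float(res.fun)
    return np.asarray(p0), float(f0)


def _fit_two_group(xa: np.ndarray, xb: np.ndarray):
    """Nested ZINB fits for one gene: pooled, constrained, full.

    Returns dict of (params, nll) for models 'pooled' (pi, mu, theta shared),
    'eq_zero' (shared pi), 'eq_abund' (shared mu) and 'full', with theta
    shared across groups in every model.
    """
    va, wa = _aggregate(xa)
    vb, wb = _aggregate(xb)

    def nll_pooled(p):
        pi, mu, theta = p
        return (_zinb_nll_terms(va, wa, pi, mu, theta)
                + _zinb_nll_terms(vb, wb, pi, mu, theta))

    def nll_eq_zero(p):
        pi, mu_a, mu_b, theta = p
        return (_zinb_nll_terms(va, wa, pi, mu_a, theta)
                + _zinb_nll_terms(vb, wb, pi, mu_b, theta))

    def nll_eq_abund(p):
        pi_a, pi_b, mu, theta = p
        return (_zinb_nll_terms(va, wa, pi_a, mu, theta)
                + _zinb_nll_terms(vb, wb, pi_b, mu, theta))

    def nll_full(p):
        pi_a, pi_b, mu_a, mu_b, theta = p
        return (_zinb_nll_terms(va, wa, pi_a, mu_a, theta)
                + _zinb_nll_terms(vb, wb, pi_b, mu_b, theta))

    b_pi = (0.0, _PI_MAX)
    b_mu = (_EPS, None)
    b_th = (1e-4, 1e6)

    init = _moment_init(np.concatenate([xa, xb]))
    pooled, f_pooled = _fit_bounded(nll_pooled, init, [b_pi, b_mu, b_th])

    pi_p, mu_p, th_p = pooled
    ez, f_ez = _fit_bounded(nll_eq_zero, (pi_p, mu_p, mu_p, th_p),
                            [b_pi, b_mu, b_mu, b_th])
    ea, f_ea = _fit_bounded(nll_eq_abund, (pi_p, pi_p, mu_p, th_p),
                            [b_pi, b_pi, b_mu, b_th])

    # start the full fit from whichever constrained optimum is better, so the
    # full likelihood can never fall below a nested one
    start_ez = (ez[0], ez[0], ez[1], ez[2], ez[3])
    start_ea = (ea[0], ea[1], ea[2], ea[2], ea[3])
    start = start_ez if f_ez <= f_ea else start_ea
    full, f_full = _fit_bounded(nll_full, start, [b_pi, b_pi, b_mu, b_mu, b_th])
    f_full = min(f_full, f_ez, f_ea)  # guard nesting against optimizer noise

    return {
        "pooled": (pooled, f_pooled),
        "eq_zero": (ez, f_ez),
        "eq_abund": (ea, f_ea),
        "full": (full, f_full),
    }


def de_two_group(
    counts: np.ndarray,
    gene_ids: list[str],
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """ZINB likelihood-ratio differential expression between two cell groups.

    ``counts`` is cells x genes (raw integers); ``cells_a`` / ``cells_b`` are
    row indices or boolean masks of the two groups (>= 10 cells each). Per
    gene three LRTs against the full two-group fit are computed: overall
    (pooled null, 2 df), zero-part (shared pi, 1 df) and abundance (shared
    mu, 1 df); dispersion is shared throughout. BH correction runs across
    genes on the overall p. Significant genes are classed DEs / DEa / DEg by
    which component tests reject at BH-corrected 0.05; when neither component
    reaches significance on its own the smaller component p decides between
    DEs and DEa. Genes all-zero in both groups are skipped.
    """
    counts = np.asarray(counts)
    xa_all = counts[np.asarray(cells_a)]
    xb_all = counts[np.asarray(cells_b)]
    if xa_all.shape[0] < 10 or xb_all.shape[0] < 10:
        raise ValueError("both groups need at least 10 cells")

    rows = []
    for j, gene in enumerate(gene_ids):
        xa = np.round(xa_all[:, j]).astype(int)
        xb = np.round(xb_all[:, j]).astype(int)
        if (xa == 0).all() and (xb == 0).all():
            continue
        fits = _fit_two_group(xa, xb)
        f_full = fits["full"][1]
        lr_overall = max(0.0, 2.0 * (fits["pooled"][1] - f_full))
        lr_zero = max(0.0, 2.0 * (fits["eq_zero"][1] - f_full))
        lr_abund = max(0.0, 2.0 * (fits["eq_abund"][1] - f_full))
        full = fits["full"][0]
        rows.append({
            "gene": gene,
            "pi_A": full[0], "pi_B": full[1],
            "mu_A": full[2], "mu_B": full[3], "theta": full[4],
            "p_overall": scipy.stats.chi2.sf(lr_overall, df=2),
            "p_zero": scipy.stats.chi2.sf(lr_zero, df=1),
            "p_abund": scipy.stats.chi2.sf(lr_abund, df=1),
        })
    if not rows:
        raise ValueError("no gene with any non-zero count in either group")
    out = pd.DataFrame(rows)
    out["q_overall"] = bh_fdr(out["p_overall"].to_numpy())
    out["q_zero"] = bh_fdr(out["p_zero"].to_numpy())
    out["q_abund"] = bh_fdr(out["p_abund"].to_numpy())

    classes = []
    for _, r in out.iterrows():
        if r["q_overall"] >= q_threshold:
            classes.append("none")
            continue
        zero_sig = r["q_zero"] < 0.05
        abund_sig = r["q_abund"] < 0.05
        if zero_sig and abund_sig:
            classes.append("DEg")
        elif zero_sig:
            classes.append("DEs")
        elif abund_sig:
            classes.append("DEa")
        else:
            classes.append("DEs" if r["p_zero"] < r["p_abund"] else "DEa")
    out["de_class"] = classes
    return out
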