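"""Phase 2 — gene association network from a shrinkage Gaussian graphical model.

With far fewer observations than genes the sample covariance S is singular,
so the stage uses the analytic shrinkage estimator

    Sigma* = lambda T + (1 - lambda) S,

where T keeps the sample variances on the diagonal and zeros elsewhere and
lambda is the closed-form optimal intensity (estimated variance of the
off-diagonal correlations over their squared sum), clipped to [0, 1].
Full-order partial correlations follow from the precision matrix
Omega = (Sigma*)^-1 via

    pcor(i, k) = -omega_ik / sqrt(omega_ii omega_kk).

Edge significance fits the null partial-correlation density
f0(r; kappa) ∝ (1 - r^2)^((kappa-3)/2) — the distribution of an empty-graph
partial correlation with kappa effective degrees of freedom — by truncated
maximum likelihood on the central bulk of |pcor|, and reports two-sided tail
p-values with Benjamini-Hochberg adjustment.  Edges enter the network either
as the top fraction of |pcor| or below an adjusted-p threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import betainc, betaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PCorNetwork",
    "shrink_covariance",
    "partial_correlations",
    "edge_significance",
    "select_edges",
    "build_pcor_network",
]

logger = logging.getLogger(__name__)


def shrink_covariance(samples: np.ndarray) -> tuple[np.ndarray, float]:
    """Shrinkage covariance estimate from an observations × genes matrix.

    Shrinks the off-diagonal correlations towards zero with the analytic
    optimal intensity; the diagonal keeps the unbiased sample variances, so
    the estimate is positive definite whenever lambda > 0.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise ValueError("samples must be a 2-D observations × genes matrix")
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 observations")
    if p < 2:
        raise ValueError("need at least 2 genes")
    xc = x - x.mean(axis=0)
    variances = (xc**2).sum(axis=0) / (n - 1)
    if np.any(variances <= 0):
        bad = np.flatnonzero(variances <= 0).tolist()
        raise ValueError(f"zero-variance gene columns: {bad}")
    xs = xc / np.sqrt(variances)
    # Correlations r_ij and the estimated variance of each r_ij
    # (Schafer-Strimmer): w_kij = z_ki z_kj, var(r_ij) = n/(n-1)^3 sum (w - wbar)^2.
    r = (xs.T @ xs) / (n - 1)
    w_bar = r * (n - 1) / n
    sum_w2 = (xs**2).T @ (xs**2)
    var_r = n / (n - 1) ** 3 * (sum_w2 - n * w_bar**2)
    off = ~np.eye(p, dtype=bool)
    denom = float((r[off] ** 2).sum())
    if denom == 0:
        lam = 1.0
    else:
        lam = float(var_r[off].sum()) / denom
    lam = min(1.0, max(0.0, lam))
    r_shrunk = (1.0 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)
    sd = np.sqrt(variances)
    sigma = r_shrunk * np.outer(sd, sd)
    return sigma, lam


def partial_correlations(sigma: np.ndarray) -> np.ndarray:
    """Full-order partial correlations from a positive-definite covariance.

    Returns a symmetric matrix with unit diagonal (convention).
    """
    sigma = np.asarray(sigma, dtype=float)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance is singular or not positive definite; apply shrinkage first"
        ) from exc
    eye = np.eye(sigma.shape[0])
    omega = np.linalg.solve(chol.T, np.linalg.solve(chol, eye))
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    pcor = (pcor + pcor.T) / 2.0
    np.fill_diagonal(pcor, 1.0)
    return pcor


# ---------------------------------------------------------------------------
# edge significance: null mixture over partial correlations


def _log_f0_unnorm(r_abs: np.ndarray, kappa: float) -> np.ndarray:
    return (kappa - 3.0) / 2.0 * np.log1p(-np.clip(r_abs, 0, 1 - 1e-12) ** 2)


def _f0_cdf_abs(r_abs: np.ndarray, kappa: float) -> np.ndarray:
    """P(|R| <= r) under f0(r; kappa):  |R|^2 ~ Beta(1/2, (kappa-1)/2)."""
    r2 = np.clip(np.asarray(r_abs, dtype=float) ** 2, 0.0, 1.0)
    return betainc(0.5, (kappa - 1.0) / 2.0, r2)


def _fit_kappa(abs_pcor: np.ndarray, central_quantile: float = 0.75) -> tuple[float, float]:
    """Truncated-null ML fit of kappa on the central bulk of |pcor|.

    Treats |pcor| values at or below their ``central_quantile`` as draws from
    f0 truncated to [0, r_c] and maximizes that truncated likelihood over
    kappa; eta0 follows as the central count divided by the fitted null mass
    of the central region, clipped to [0, 1].
    """
    r_c = float(np.quantile(abs_pcor, central_quantile))
    central = abs_pcor[abs_pcor <= r_c]
    if r_c <= 0 or len(central) < 5:
        logger.warning("degenerate central region; kappa fixed at a diffuse default")
        return 1e4, 1.0

    def neg_loglik(log_kappa: float) -> float:
        kappa = math.exp(log_kappa)
        mass = float(_f0_cdf_abs(np.array([r_c]), kappa)[0])
        if mass <= 0:
            return np.inf
        ll = _log_f0_unnorm(central, kappa).sum()
        # density of |R|: 2 (1-r^2)^((kappa-3)/2) / B(1/2, (kappa-1)/2)
        log_const = betaln(0.5, (kappa - 1.0) / 2.0) - math.log(2.0)
        ll -= len(central) * (log_const + math.log(mass))
        return -ll

    res = minimize_scalar(neg_loglik, bounds=(math.log(3.1), math.log(1e6)), method="bounded")
    kappa = float(math.exp(res.x))
    null_mass = float(_f0_cdf_abs(np.array([r_c]), kappa)[0])
    eta0 = min(1.0, len(central) / (len(abs_pcor) * max(null_mass, 1e-12)))
    return kappa, eta0


@dataclass(frozen=True)
class EdgeSignificance:
    pairs: list[tuple[int, int]]
    pcor: np.ndarray
    p: np.ndarray
    p_adjusted: np.ndarray
    kappa: float
    eta0: float


def edge_significance(pcor: np.ndarray, n_observations: int | None = None) -> EdgeSignificance:
    """Two-sided p-values for non-zero partial correlation on every gene pair.

    The null density f0(r; kappa) ∝ (1 - r^2)^((kappa-3)/2) is fitted to the
    central 75% of |pcor| by truncated maximum likelihood; kappa plays the
    role of an effective sample size, so ``n_observations`` is only used as a
    sanity log.  p-values are Benjamini-Hochberg adjusted across all pairs.
    """
    pcor = np.asarray(pcor, dtype=float)
    p_genes = pcor.shape[0]
    pairs = list(combinations(range(p_genes), 2))
    if len(pairs) < 10:
        raise ValueError("need at least 10 gene pairs to fit the null mixture")
    values = np.array([pcor[i, j] for i, j in pairs])
    abs_vals = np.abs(values)
    degenerate = abs_vals >= 1.0
    if degenerate.any():
        logger.warning("%d degenerate |pcor|=1 pairs assigned p=0", int(degenerate.sum()))
    kappa, eta0 = _fit_kappa(abs_vals[~degenerate] if degenerate.any() else abs_vals)
    if n_observations is not None:
        logger.info("fitted kappa=%.1f (n_observations=%d), eta0=%.3f", kappa, n_observations, eta0)
    pvals = 1.0 - _f0_cdf_abs(abs_vals, kappa)
    pvals = np.where(degenerate, 0.0, np.clip(pvals, 0.0, 1.0))
    p_adj = multipletests(np.clip(pvals, np.nextafter(0.0, 1.0), 1.0), method="fdr_bh")[1]
    return EdgeSignificance(pairs, values, pvals, p_adj, kappa, eta0)


@dataclass(frozen=True)
class PCorNetwork:
    """Shrunken covariance, partial correlations and per-pair significance."""

    gene_ids: list[str]
    sigma: np.ndarray
    shrinkage: float
    pcor: np.ndarray
    significance: EdgeSignificance

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def build_pcor_network(samples: np.ndarray, gene_ids: list[str]) -> PCorNetwork:
    """Convenience chain: shrink covariance -> pcor -> edge significance."""
    sigma, lam = shrink_covariance(samples)
    pcor = partial_correlations(sigma)
    sig = edge_significance(pcor, n_observations=samples.shape[0])
    return PCorNetwork(list(gene_ids), sigma, lam, pcor, sig)


def select_edges(
    network: PCorNetwork,
    mode: str = "top_fraction",
    q: float = 0.01,
    alpha: float = 0.01,
) -> nx.Graph:
    """Build the gene association network from the strongest/most significant pairs.

    ``top_fraction`` ranks all unordered pairs by |pcor| descending and keeps
    the top ``ceil(q * n_pairs)`` (pairs tied with the cutoff value are all
    kept, the overshoot is logged); ``alpha`` keeps pairs with adjusted
    p < alpha; ``combined`` intersects the two.  Both activation (pcor > 0)
    and suppression (pcor < 0) edges are retained; isolated nodes are dropped.
    """
    if mode not in {"top_fraction", "alpha", "combined"}:
        raise ValueError(f"unknown selection mode {mode!r}")
    sig = network.significance
    n_pairs = len(sig.pairs)
    abs_vals = np.abs(sig.pcor)
    keep = np.ones(n_pairs, dtype=bool)
    if mode in {"top_fraction", "combined"}:
        if not 0 < q <= 1:
            raise ValueError("q must lie in (0, 1]")
        n_keep = math.ceil(q * n_pairs)
        order = np.argsort(-abs_vals, kind="stable")
        cutoff = abs_vals[order[n_keep - 1]]
        top = abs_vals >= cutoff
        if top.sum() > n_keep:
            logger.info(
                "top-fraction tie at |pcor|=%.6g keeps %d pairs (requested %d)",
                cutoff,
                int(top.sum()),
                n_keep,
            )
        keep &= top
    if mode in {"alpha", "combined"}:
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        keep &= sig.p_adjusted < alpha
    graph = nx.Graph()
    for idx in np.flatnonzero(keep):
        i, j = sig.pairs[idx]
        graph.add_edge(
            network.gene_ids[i],
            network.gene_ids[j],
            pcor=float(sig.pcor[idx]),
            p=float(sig.p[idx]),
            p_adjusted=float(sig.p_adjusted[idx]),
        )
    if graph.number_of_edges() == 0:
        logger.warning("edge selection produced an empty network")
    return graph
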