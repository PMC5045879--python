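"""Phase 1 — differential expression over consecutive-time contrasts.

For a balanced time-course design (T time points, r replicates each) the
stage fits, per gene g, the contrast estimates

    beta_gk = mean(t_{k+1}) - mean(t_k),   k = 1..K,  K = T - 1,

with the pooled within-time residual variance s_g^2 on d_g = n - T degrees of
freedom, then shrinks the gene-wise variances towards a common prior by
empirical Bayes.  The prior (d0, s0^2) is estimated by moment matching on
log s_g^2 (digamma/trigamma closed forms), giving the posterior variance

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

and the moderated t statistic t~_gk = beta_gk / (s~_g sqrt(v_gk)) with
v_gk = 1/r_k + 1/r_{k+1}.  An omnibus moderated F over the K (correlated)
contrasts is tested against F(K, d0 + d_g); genes below the p-value
threshold are differentially expressed.  A direction filter then retains
genes whose per-time sign profile holds a same-direction run of at least
``min_run`` consecutive time points, yielding disjoint up/down query sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from stressnet.io import ExpressionSeries

__all__ = [
    "ContrastFit",
    "ModeratedStats",
    "DEGTable",
    "quantile_normalize",
    "fit_contrasts",
    "moderate",
    "select_degs",
    "consecutive_direction_filter",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# quantile normalization (the quantile step of RMA on summarized values)


def quantile_normalize(series: ExpressionSeries, log2_transform: bool = False) -> ExpressionSeries:
    """Force every sample column onto the common mean-quantile distribution.

    After normalization all columns share the identical sorted value multiset
    (the column-wise mean quantile); within-column ranks are preserved and
    ties map to the average of the tied reference quantiles.
    """
    x = series.matrix()
    if log2_transform:
        x = np.log2(x)
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.all(col == col[0]):
            logger.warning("constant column %d mapped to mean quantiles by average rank", j)
        ranks = stats.rankdata(col, method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    values = pd.DataFrame(out, index=series.values.index, columns=series.values.columns)
    return ExpressionSeries(values, series.times, series.replicates)


# ---------------------------------------------------------------------------
# per-gene contrast fits


@dataclass(frozen=True)
class ContrastFit:
    """Per-gene consecutive-time contrast estimates and residual variances."""

    gene_ids: list[str]
    times: np.ndarray  # distinct time points, ascending (length T)
    beta: np.ndarray  # genes × K contrast estimates, K = T - 1
    s2: np.ndarray  # pooled residual variance per gene
    df_residual: float  # d_g, equal for all genes in a balanced design
    v: np.ndarray  # unscaled variance factor per contrast (length K)
    time_means: np.ndarray  # genes × T per-time means (for direction calls)
    rep_counts: np.ndarray  # replicates per time point (length T)

    @property
    def n_contrasts(self) -> int:
        return self.beta.shape[1]

    def contrast_covariance_factor(self) -> np.ndarray:
        """K × K unscaled covariance of the contrast vector, C diag(1/r) C'."""
        T = len(self.times)
        C = np.zeros((T - 1, T))
        for k in range(T - 1):
            C[k, k] = -1.0
            C[k, k + 1] = 1.0
        return C @ np.diag(1.0 / self.rep_counts) @ C.T


def fit_contrasts(series: ExpressionSeries) -> ContrastFit:
    """Fit per-gene means and consecutive-time contrasts.

    Requires a balanced design with at least two replicates per time point
    (otherwise the within-time residual variance is inestimable).
    """
    times = series.unique_times
    groups = [np.flatnonzero(series.times == t) for t in times]
    counts = np.array([len(g) for g in groups])
    if np.any(counts < 2):
        bad = times[counts < 2].tolist()
        raise ValueError(f"time points with fewer than 2 replicates: {bad}")
    if len(set(counts.tolist())) != 1:
        raise ValueError(f"unbalanced design (replicates per time: {counts.tolist()})")
    x = series.matrix()
    time_means = np.column_stack([x[:, g].mean(axis=1) for g in groups])
    beta = np.diff(time_means, axis=1)
    rss = np.zeros(x.shape[0])
    for t_idx, g in enumerate(groups):
        resid = x[:, g] - time_means[:, [t_idx]]
        rss += (resid**2).sum(axis=1)
    df_residual = float(series.n_samples - len(times))
    s2 = rss / df_residual
    v = 1.0 / counts[:-1] + 1.0 / counts[1:]
    return ContrastFit(
        gene_ids=series.gene_ids,
        times=times,
        beta=beta,
        s2=s2,
        df_residual=df_residual,
        v=v.astype(float),
        time_means=time_means,
        rep_counts=counts,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the scaled inverse-chi-square prior (d0, s0^2).

    Matches the mean and variance of log s_g^2 to the scaled-F model for the
    sample variances; returns ``(inf, s0^2)`` when the observed spread of
    log-variances is no larger than expected under a common variance.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive sample variances to estimate the prior")
    if not ok.all():
        logger.warning("%d zero sample variances excluded from prior estimation", (~ok).sum())
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        logger.warning("log-variance spread at or below sampling noise; prior df set to +inf")
        return math.inf, math.exp(emean)
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = math.exp(emean + digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s02


@dataclass(frozen=True)
class ModeratedStats:
    """Moderated t/F statistics with the fitted variance prior."""

    gene_ids: list[str]
    times: np.ndarray
    d0: float
    s02: float
    s2_post: np.ndarray  # posterior variances s~_g^2
    t: np.ndarray  # genes × K moderated t per consecutive contrast
    F: np.ndarray  # moderated omnibus F per gene
    df_num: int
    df_denom: float  # d0 + d_g (may be inf)
    p: np.ndarray
    p_adjusted: np.ndarray
    time_means: np.ndarray  # carried through for direction calls
    baseline_deltas: np.ndarray  # genes × (T-1) mean(t) - mean(t0)

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"F": self.F, "p": self.p, "p_adjusted": self.p_adjusted}, index=self.gene_ids
        )
        for k in range(self.t.shape[1]):
            df[f"t_{k + 1}"] = self.t[:, k]
        return df


def moderate(fit: ContrastFit, d0_override: float | None = None) -> ModeratedStats:
    """Shrink gene variances and compute moderated t and omnibus F statistics.

    ``d0_override`` forces the prior degrees of freedom (0 recovers the
    classical per-gene statistics; useful as an oracle check).
    """
    if len(fit.gene_ids) < 10 and d0_override is None:
        raise ValueError("hyperparameter estimation needs at least 10 genes")
    if fit.df_residual < 1:
        raise ValueError("residual degrees of freedom must be at least 1")
    if d0_override is not None:
        d0 = float(d0_override)
        _, s02 = estimate_prior(fit.s2, fit.df_residual) if d0 > 0 else (0.0, float("nan"))
        if d0 == 0:
            s02 = float(np.median(fit.s2))  # irrelevant to the statistics at d0=0
    else:
        d0, s02 = estimate_prior(fit.s2, fit.df_residual)
    dg = fit.df_residual
    if math.isinf(d0):
        s2_post = np.full_like(fit.s2, s02)
        df_denom = math.inf
    else:
        s2_post = (d0 * s02 + dg * fit.s2) / (d0 + dg)
        df_denom = d0 + dg
    K = fit.n_contrasts
    t_mod = fit.beta / np.sqrt(s2_post[:, None] * fit.v[None, :])
    # Omnibus F over the correlated contrast vector: beta' V^-1 beta / (K s~^2).
    V = fit.contrast_covariance_factor()
    Vinv = np.linalg.inv(V)
    quad = np.einsum("gi,ij,gj->g", fit.beta, Vinv, fit.beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = quad / (K * s2_post)
    F = np.where(s2_post > 0, F, np.inf)
    if math.isinf(df_denom):
        p = stats.chi2.sf(K * F, K)
    else:
        p = stats.f.sf(F, K, df_denom)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    baseline_deltas = fit.time_means[:, 1:] - fit.time_means[:, [0]]
    return ModeratedStats(
        gene_ids=fit.gene_ids,
        times=fit.times,
        d0=d0,
        s02=s02,
        s2_post=s2_post,
        t=t_mod,
        F=F,
        df_num=K,
        df_denom=df_denom,
        p=p,
        p_adjusted=p_adj,
        time_means=fit.time_means,
        baseline_deltas=baseline_deltas,
    )


# ---------------------------------------------------------------------------
# DEG selection and the consecutive-direction filter


@dataclass(frozen=True)
class DEGTable:
    """Selected genes with p-values, per-time direction signs and effects.

    ``signs``/``deltas`` are genes × non-baseline time points; a sign is
    relative to the t=0 baseline by default (``direction='baseline'``) or to
    the previous time point (``direction='consecutive'``).
    """

    table: pd.DataFrame  # columns: p, p_adjusted
    signs: pd.DataFrame  # ±1/0 per non-baseline time point
    deltas: pd.DataFrame  # signed log2 effects matching `signs`
    alpha: float
    use_adjusted: bool
    direction: str

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def select_degs(
    mstats: ModeratedStats,
    alpha: float = 0.01,
    use_adjusted: bool = False,
    direction: str = "baseline",
) -> DEGTable:
    """Select genes with (adjusted) moderated-F p below ``alpha``.

    Direction signs per non-baseline time point are computed against the t=0
    baseline (default) or the previous time point.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if direction not in {"baseline", "consecutive"}:
        raise ValueError("direction must be 'baseline' or 'consecutive'")
    pvals = mstats.p_adjusted if use_adjusted else mstats.p
    keep = pvals < alpha if alpha < 1 else np.ones_like(pvals, dtype=bool)
    genes = [g for g, k in zip(mstats.gene_ids, keep) if k]
    if direction == "baseline":
        deltas = mstats.baseline_deltas[keep]
    else:
        deltas = np.diff(mstats.time_means, axis=1)[keep]
    time_cols = [f"t{_fmt(t)}" for t in mstats.times[1:]]
    table = pd.DataFrame(
        {"p": mstats.p[keep], "p_adjusted": mstats.p_adjusted[keep]}, index=genes
    )
    deltas_df = pd.DataFrame(deltas, index=genes, columns=time_cols)
    signs_df = pd.DataFrame(np.sign(deltas).astype(int), index=genes, columns=time_cols)
    return DEGTable(table, signs_df, deltas_df, alpha, use_adjusted, direction)


def _fmt(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else str(t)


def _longest_run_effect(signs: np.ndarray, deltas: np.ndarray, target: int, min_run: int) -> float:
    """Largest |cumulative effect| over runs of >= min_run consecutive `target` signs."""
    best = 0.0
    i = 0
    n = len(signs)
    while i < n:
        if signs[i] == target:
            j = i
            while j < n and signs[j] == target:
                j += 1
            if j - i >= min_run:
                best = max(best, abs(float(deltas[i:j].sum())))
            i = j
        else:
            i += 1
    return best


def consecutive_direction_filter(
    table: DEGTable, min_run: int = 2
) -> tuple[frozenset[str], frozenset[str]]:
    """Split DEGs into disjoint up/down sets by the consecutive-run rule.

    A gene joins the up (down) set iff its sign profile over the non-baseline
    time points holds at least ``min_run`` consecutive positive (negative)
    signs.  A gene qualifying for both directions is assigned to the one with
    the larger |cumulative effect| over its qualifying run; exact ties are
    excluded (the query sets must stay disjoint) and the decision is logged.
    """
    n_times = table.signs.shape[1]
    if min_run > n_times:
        raise ValueError(f"min_run={min_run} exceeds the {n_times} non-baseline time points")
    up: set[str] = set()
    down: set[str] = set()
    for gene in table.genes:
        s = table.signs.loc[gene].to_numpy()
        d = table.deltas.loc[gene].to_numpy()
        up_eff = _longest_run_effect(s, d, +1, min_run)
        down_eff = _longest_run_effect(s, d, -1, min_run)
        if up_eff > 0 and down_eff > 0:
            if up_eff > down_eff:
                up.add(gene)
            elif down_eff > up_eff:
                down.add(gene)
            else:
                logger.warning("gene %s qualifies for both directions with equal effect; excluded", gene)
        elif up_eff > 0:
            up.add(gene)
        elif down_eff > 0:
            down.add(gene)
    return frozenset(up), frozenset(down)
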