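"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator returns the artifact plus a :class:`SyntheticTruth` carrying
the planted ground truth, so recovery metrics can be computed without
re-deriving labels.  All randomness flows through numpy's PCG64 generator;
one seed fans out to per-stage substreams through ``SeedSequence.spawn``, so
a fixed seed gives bit-identical outputs across runs and platforms.

The time-course generator emulates a stretched-cell microarray design:
4 time points (0, 2, 4, 24 h) × 2 replicates on a log2 scale, gene-wise
variances drawn from a scaled inverse-chi-square (the empirical-Bayes model
class), and a planted fraction of genes carrying step-shaped mean shifts
whose sign profile always holds a run of >= 2 consecutive same-direction
time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from stressnet.io import ExpressionSeries, SignatureReference

__all__ = [
    "SyntheticTruth",
    "generate_timecourse",
    "generate_ggm_sample",
    "generate_network",
    "generate_signature_reference",
]

DEFAULT_TIMES = (0.0, 2.0, 4.0, 24.0)

# Step profiles (per non-baseline time, in units of the effect size) whose
# sign pattern holds >= 2 consecutive same-direction time points.
_PROFILES = (
    (1.0, 1.0, 1.0),
    (0.0, 1.0, 1.0),
    (1.0, 1.0, 0.0),
    (0.5, 1.0, 1.0),
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted by a generator."""

    seed: int
    deg_labels: dict[str, str] | None = None  # gene -> up | down | null
    effects: pd.DataFrame | None = None  # genes × non-baseline times, signed log2 shifts
    precision_edges: frozenset[tuple[int, int]] | None = None
    precision: np.ndarray | None = None
    planted_communities: tuple[frozenset, ...] | None = None
    reverser_drugs: frozenset[str] = field(default_factory=frozenset)

    def deg_genes(self) -> frozenset[str]:
        if self.deg_labels is None:
            raise ValueError("no DEG labels planted")
        return frozenset(g for g, lab in self.deg_labels.items() if lab != "null")


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_timecourse(
    n_genes: int = 1000,
    deg_fraction: float = 0.05,
    times: tuple[float, ...] = DEFAULT_TIMES,
    n_reps: int = 2,
    effect_size: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    prior_df: float = 4.0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
) -> tuple[ExpressionSeries, SyntheticTruth]:
    """Simulate a log2 expression time course with planted differential genes.

    Null genes have time-constant means; a ``deg_fraction`` of genes carry a
    step profile of amplitude ``effect_size`` (half up-, half down-regulated)
    added from t > 0 onward.  Per-gene noise variances are drawn from a
    scaled inverse-chi-square with ``prior_df`` degrees of freedom and scale
    ``noise_sd**2``, so variance-moderation hyperparameters are recoverable.
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    if not 0 <= deg_fraction <= 1:
        raise ValueError("deg_fraction must lie in [0, 1]")
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    times_arr = np.asarray(times, dtype=float)
    if len(times_arr) < 2 or np.any(np.diff(times_arr) <= 0):
        raise ValueError("times must be strictly increasing with at least 2 points")
    n_deg = int(round(deg_fraction * n_genes))
    if deg_fraction > 0 and n_deg < 1:
        raise ValueError("deg_fraction too small: fewer than one planted gene")
    rng_label, rng_var, rng_noise, rng_base = _substreams(seed, 4)

    genes = [f"g{i:05d}" for i in range(n_genes)]
    deg_idx = rng_label.choice(n_genes, size=n_deg, replace=False)
    labels = {g: "null" for g in genes}
    n_non_baseline = len(times_arr) - 1
    effects = np.zeros((n_genes, n_non_baseline))
    for j, idx in enumerate(np.sort(deg_idx)):
        sign = 1.0 if j % 2 == 0 else -1.0
        profile = _PROFILES[rng_label.integers(len(_PROFILES))]
        prof = np.array(profile[:n_non_baseline])
        if len(prof) < n_non_baseline:
            prof = np.pad(prof, (0, n_non_baseline - len(prof)), constant_values=prof[-1])
        effects[idx] = sign * effect_size * prof
        labels[genes[idx]] = "up" if sign > 0 else "down"

    # scaled inverse-chi-square variances: sigma^2 = d0 s0^2 / chi2_d0
    s02 = noise_sd**2
    sigma2 = prior_df * s02 / rng_var.chisquare(prior_df, size=n_genes)
    baseline = rng_base.normal(baseline_mean, baseline_sd, size=n_genes)

    col_times = np.repeat(times_arr, n_reps)
    col_reps = np.tile(np.arange(1, n_reps + 1), len(times_arr))
    mean_by_time = np.concatenate([np.zeros((n_genes, 1)), effects], axis=1)
    means = baseline[:, None] + np.repeat(mean_by_time, n_reps, axis=1)
    noise = rng_noise.standard_normal((n_genes, len(col_times))) * np.sqrt(sigma2)[:, None]
    values = pd.DataFrame(
        means + noise,
        index=genes,
        columns=[f"t{_fmt(t)}_rep{r}" for t, r in zip(col_times, col_reps)],
    )
    series = ExpressionSeries(values, col_times, col_reps)
    effects_df = pd.DataFrame(
        effects, index=genes, columns=[f"t{_fmt(t)}" for t in times_arr[1:]]
    )
    truth = SyntheticTruth(seed=seed, deg_labels=labels, effects=effects_df)
    return series, truth


def _fmt(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else str(t)


# ---------------------------------------------------------------------------
# multivariate-normal samples from planted sparse precision matrices


def build_precision(
    structure: str,
    n_genes: int,
    edge_weight: float = -1.0,
    diagonal: float = 2.0,
    density: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Construct a sparse precision matrix (identity, chain or random-sparse).

    ``random`` places ``edge_weight`` on a Bernoulli(``density``) set of
    off-diagonal pairs and then raises the diagonal to strict diagonal
    dominance.  The result is verified positive definite.
    """
    omega = np.eye(n_genes) * diagonal
    if structure == "identity":
        omega = np.eye(n_genes)
    elif structure == "chain":
        for i in range(n_genes - 1):
            omega[i, i + 1] = omega[i + 1, i] = edge_weight
    elif structure == "random":
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(n_genes, k=1)
        mask = rng.random(len(iu[0])) < density
        omega[iu[0][mask], iu[1][mask]] = edge_weight
        omega[iu[1][mask], iu[0][mask]] = edge_weight
        row_off = np.abs(omega).sum(axis=1) - np.abs(np.diag(omega))
        np.fill_diagonal(omega, np.maximum(diagonal, row_off + 0.5))
    else:
        raise ValueError(f"unknown precision structure {structure!r}")
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:
        eigmin = float(np.linalg.eigvalsh(omega).min())
        raise ValueError(
            f"precision spec is not positive definite (min eigenvalue {eigmin:.3g})"
        ) from exc
    return omega


def generate_ggm_sample(
    structure: str | np.ndarray,
    n_genes: int,
    n_samples: int,
    seed: int = 0,
    **spec_kwargs,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Draw i.i.d. multivariate-normal rows with covariance = inverse precision.

    ``structure`` may be a descriptor name understood by
    :func:`build_precision` or an explicit precision matrix.
    """
    if isinstance(structure, np.ndarray):
        omega = np.asarray(structure, dtype=float)
        if omega.shape != (n_genes, n_genes):
            raise ValueError("explicit precision matrix has the wrong shape")
        try:
            np.linalg.cholesky(omega)
        except np.linalg.LinAlgError as exc:
            raise ValueError("precision matrix is not positive definite") from exc
    else:
        omega = build_precision(structure, n_genes, seed=seed, **spec_kwargs)
    sigma = np.linalg.inv(omega)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    x = rng.multivariate_normal(np.zeros(n_genes), sigma, size=n_samples, method="cholesky")
    edges = frozenset(
        (i, j)
        for i in range(n_genes)
        for j in range(i + 1, n_genes)
        if omega[i, j] != 0.0
    )
    truth = SyntheticTruth(seed=seed, precision_edges=edges, precision=omega)
    return x, truth


# ---------------------------------------------------------------------------
# graphs with planted k-clique communities


def generate_network(
    n_nodes: int,
    planted_communities: list[set] | list[list],
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Planted-partition graph: dense inside communities, sparse between.

    Communities may overlap; an edge whose endpoints share at least one
    community appears with probability ``p_in``, all other pairs with
    ``p_out``.
    """
    if not p_in > p_out:
        raise ValueError("p_in must exceed p_out")
    communities = [frozenset(c) for c in planted_communities]
    for c in communities:
        if not c <= set(range(n_nodes)):
            raise ValueError("community nodes must index into range(n_nodes)")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    graph = nx.Graph()
    graph.add_nodes_from(range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            same = any(i in c and j in c for c in communities)
            p = p_in if same else p_out
            if p > 0 and rng.random() < p:
                graph.add_edge(i, j)
    truth = SyntheticTruth(seed=seed, planted_communities=tuple(communities))
    return graph, truth


# ---------------------------------------------------------------------------
# signature references with planted query-reversing perturbations


def generate_signature_reference(
    universe: list[str],
    n_perturbations: int,
    query,
    n_reversers: int,
    noise: float = 0.05,
    seed: int = 0,
    instances_per_drug: int = 1,
) -> tuple[SignatureReference, SyntheticTruth]:
    """Rank-matrix reference with ``n_reversers`` planted reversal drugs.

    A reverser ranks the query's down-genes at the very top and up-genes at
    the very bottom before noise; all other perturbations are uniformly
    random permutations.  ``noise`` jitters the reverser rank keys by a
    Gaussian of standard deviation ``noise * N`` before re-ranking.
    ``n_perturbations`` counts drugs; each drug contributes
    ``instances_per_drug`` columns named ``<drug>_i<j>`` (a lone instance
    keeps the bare drug name), mirroring how perturbation references profile
    the same compound under several conditions.
    """
    if n_reversers > n_perturbations:
        raise ValueError("more reversers than perturbations")
    universe = list(universe)
    n = len(universe)
    up = sorted(query.up)
    down = sorted(query.down)
    if set(up) & set(down):
        raise ValueError("query up/down sets overlap")
    if not set(up) <= set(universe) or not set(down) <= set(universe):
        raise ValueError("query genes must lie in the universe")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    drug_ids = [f"drug{i:03d}" for i in range(n_perturbations)]
    reversers = frozenset(drug_ids[:n_reversers])
    if instances_per_drug < 1:
        raise ValueError("instances_per_drug must be at least 1")
    pert_ids = [
        drug if instances_per_drug == 1 else f"{drug}_i{j + 1}"
        for drug in drug_ids
        for j in range(instances_per_drug)
    ]
    pos = {g: i for i, g in enumerate(universe)}
    columns = {}
    for pid in pert_ids:
        if drug_of_instance(pid) in reversers:
            key = np.full(n, 0.5 * n)
            middle = [g for g in universe if g not in set(up) | set(down)]
            key[[pos[g] for g in middle]] = rng.permutation(len(middle)) + len(down)
            key[[pos[g] for g in down]] = np.arange(len(down))  # top of ranking
            key[[pos[g] for g in up]] = n - len(up) + np.arange(len(up))  # bottom
            if noise > 0:
                key = key + rng.normal(0.0, noise * n, size=n)
            ranks = np.empty(n, dtype=int)
            ranks[np.argsort(key, kind="stable")] = np.arange(1, n + 1)
        else:
            ranks = rng.permutation(n) + 1
        columns[pid] = ranks
    df = pd.DataFrame(columns, index=universe)
    reference = SignatureReference(df)
    truth = SyntheticTruth(seed=seed, reverser_drugs=reversers)
    return reference, truth


def drug_of_instance(instance_id: str) -> str:
    """Drug name of an instance column (strips a trailing ``_i<j>`` suffix)."""
    stem, sep, tail = instance_id.rpartition("_i")
    if sep and tail.isdigit():
        return stem
    return instance_id


def instance_drug_groups(perturbations: list[str]) -> dict[str, list[str]]:
    """Group instance columns by drug name."""
    groups: dict[str, list[str]] = {}
    for pid in perturbations:
        groups.setdefault(drug_of_instance(pid), []).append(pid)
    return groups
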