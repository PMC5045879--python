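"""Signature-reversal drug scoring against a rank-matrix perturbation reference.

Each reference column ranks the gene universe from most up-regulated (rank 1)
to most down-regulated (rank N) under one perturbation instance.  For a
disjoint up/down query signature the Kolmogorov-Smirnov-style enrichment of
a tag set with sorted positions V(1) < ... < V(t) is

    a = max_j [ j/t - V(j)/N ],   b = max_j [ V(j)/N - (j-1)/t ],
    ES = a if a >= b else -b,

and the combined connectivity score is (ES_up - ES_down)/2 when the two
enrichments disagree in sign, and 0 otherwise.  A score of -1 means perfect
reversal (query up-genes at the bottom of the ranking, down-genes at the
top) — the repositioning signal of interest.

Per-drug significance comes from a permutation test: the observed statistic
is the mean score over the drug's instances, compared against means of
random instance subsets of the same size (lower tail, add-one estimator).
Candidates are drugs with permutation p below alpha and negative mean score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from stressnet.io import SignatureReference

__all__ = [
    "QuerySignature",
    "ConnectivityResult",
    "ks_enrichment",
    "connectivity_score",
    "score_reference",
    "permutation_pvalues",
    "repositioning_candidates",
    "validation_rate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuerySignature:
    """Disjoint, non-empty up- and down-regulated gene sets."""

    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        if not self.up or not self.down:
            raise ValueError("both up and down sets must be non-empty")
        if self.up & self.down:
            raise ValueError(f"up/down sets overlap: {sorted(self.up & self.down)[:5]}")

    def validate_against(self, universe: Iterable[str]) -> None:
        universe = set(universe)
        missing = sorted((self.up | self.down) - universe)
        if missing:
            raise ValueError(f"query genes absent from the reference universe: {missing[:10]}")
        if len(self.up) >= len(universe) or len(self.down) >= len(universe):
            raise ValueError("each query set must be smaller than the universe")


def ks_enrichment(positions: Sequence[int], n_genes: int) -> float:
    """KS enrichment of a tag set at the given 1-based ranks among ``n_genes``.

    Positive values mean the tags crowd the top of the ranking, negative the
    bottom; |ES| <= 1 with equality only for a fully packed extreme.
    """
    v = np.asarray(sorted(positions), dtype=float)
    t = len(v)
    if t < 1 or t >= n_genes:
        raise ValueError("tag set must satisfy 1 <= size < n_genes")
    if len(np.unique(v)) != t:
        raise ValueError("duplicate tag positions")
    if v[0] < 1 or v[-1] > n_genes:
        raise ValueError("positions must lie in 1..n_genes")
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - v / n_genes))
    b = float(np.max(v / n_genes - (j - 1) / t))
    return a if a >= b else -b


def connectivity_score(
    query: QuerySignature, ranking: pd.Series | Mapping[str, int]
) -> tuple[float, float, float]:
    """(ES_up, ES_down, combined score) of a query against one ranking column.

    The combined score is (ES_up - ES_down)/2 when the two enrichments have
    opposite signs and 0 otherwise, so it reaches +1 only when the up-genes
    pack the top and down-genes the bottom, and negative values flag
    signature reversal.
    """
    ranking = pd.Series(ranking)
    query.validate_against(ranking.index)
    n = len(ranking)
    es_up = ks_enrichment(ranking.loc[sorted(query.up)].to_numpy(), n)
    es_down = ks_enrichment(ranking.loc[sorted(query.down)].to_numpy(), n)
    score = 0.0 if es_up * es_down >= 0 else (es_up - es_down) / 2.0
    return es_up, es_down, score


@dataclass(frozen=True)
class ConnectivityResult:
    """Per-instance scores and per-drug summary of a repositioning query."""

    instances: pd.DataFrame  # index perturbation id; ES_up, ES_down, score, drug
    drugs: pd.DataFrame  # index drug; n_instances, mean_score, p, candidate

    def candidates(self) -> list[str]:
        flagged = self.drugs[self.drugs["candidate"]]
        return list(flagged.sort_values("mean_score").index)


def score_reference(
    query: QuerySignature,
    reference: SignatureReference,
    drug_groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Score every perturbation instance of a reference against the query.

    ``drug_groups`` maps a drug name to its instance (column) identifiers;
    when omitted every instance is its own drug.
    """
    query.validate_against(reference.universe)
    if drug_groups is None:
        drug_groups = {p: [p] for p in reference.perturbations}
    drug_of = {}
    for drug, insts in drug_groups.items():
        if not insts:
            raise ValueError(f"drug {drug!r} has no instances")
        for inst in insts:
            drug_of[inst] = drug
    missing = [p for p in drug_of if p not in set(reference.perturbations)]
    if missing:
        raise ValueError(f"instances absent from the reference: {missing[:5]}")
    rows = []
    for pert in reference.perturbations:
        es_up, es_down, score = connectivity_score(query, reference.ranking(pert))
        rows.append(
            {
                "instance": pert,
                "drug": drug_of.get(pert, pert),
                "ES_up": es_up,
                "ES_down": es_down,
                "score": score,
            }
        )
    return pd.DataFrame(rows).set_index("instance")


def permutation_pvalues(
    instance_scores: pd.DataFrame,
    n_perm: int = 100_000,
    seed: int = 0,
    adjust: str = "none",
) -> pd.DataFrame:
    """Lower-tail permutation p-value for each drug's mean instance score.

    For a drug with m instances the null is the distribution of means of m
    instances drawn at random (without replacement) from all instance scores;
    p = (1 + #{null <= observed}) / (n_perm + 1), targeting reversal (the
    more negative the observed mean, the smaller p).  ``adjust='bh'`` applies
    a Benjamini-Hochberg correction across drugs to the reported ``p``.
    """
    if adjust not in {"none", "bh"}:
        raise ValueError("adjust must be 'none' or 'bh'")
    if n_perm < 1000:
        raise ValueError("n_perm must be at least 1000")
    scores = instance_scores["score"].to_numpy(dtype=float)
    pool = len(scores)
    rng = np.random.default_rng(seed)
    grouped = instance_scores.groupby("drug")["score"]
    observed = grouped.mean()
    sizes = grouped.size()
    null_by_m: dict[int, np.ndarray] = {}
    for m in sorted(sizes.unique()):
        if m > pool:
            raise ValueError(f"drug instance count {m} exceeds the pool of {pool}")
        if m == 1:
            draws = rng.integers(0, pool, size=n_perm)
            null_by_m[m] = scores[draws]
        else:
            null = np.empty(n_perm)
            chunk = max(1, min(n_perm, 20_000_000 // pool))
            done = 0
            while done < n_perm:
                size = min(chunk, n_perm - done)
                keys = rng.random((size, pool))
                idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
                null[done : done + size] = scores[idx].mean(axis=1)
                done += size
            null_by_m[m] = null
    rows = []
    for drug in observed.index:
        m = int(sizes[drug])
        obs = float(observed[drug])
        null = null_by_m[m]
        p = (1.0 + float(np.count_nonzero(null <= obs))) / (n_perm + 1.0)
        rows.append({"drug": drug, "n_instances": m, "mean_score": obs, "p": p})
    table = pd.DataFrame(rows).set_index("drug")
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        table["p"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table


def repositioning_candidates(
    drug_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Drugs with permutation p < alpha and negative mean score, best first."""
    flagged = drug_table[(drug_table["p"] < alpha) & (drug_table["mean_score"] < 0)]
    return flagged.sort_values("mean_score")


def run_query(
    query: QuerySignature,
    reference: SignatureReference,
    drug_groups: Mapping[str, Sequence[str]] | None = None,
    n_perm: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
    adjust: str = "none",
) -> ConnectivityResult:
    """Full repositioning query: score, permutation test, candidate flags."""
    instances = score_reference(query, reference, drug_groups)
    drugs = permutation_pvalues(instances, n_perm=n_perm, seed=seed, adjust=adjust)
    drugs["candidate"] = (drugs["p"] < alpha) & (drugs["mean_score"] < 0)
    return ConnectivityResult(instances=instances, drugs=drugs)


def validation_rate(candidates: Sequence[str], validated: Iterable[str]) -> float:
    """Fraction of candidate drugs confirmed by external validation data."""
    candidates = list(candidates)
    if not candidates:
        logger.info("no candidates; validation rate reported as 0")
        return 0.0
    validated = set(validated)
    return len(set(candidates) & validated) / len(candidates)
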