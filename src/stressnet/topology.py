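"""Phase 3a — topological parameters of the gene association network and SV ranking.

Eight local parameters are computed per node of the (unweighted, simple,
undirected) network:

* DC  — degree centrality, deg(v)/(n-1);
* BC  — normalized shortest-path betweenness centrality;
* CC  — closeness, (#reachable others)/(sum of distances to them), per component;
* EC  — eccentricity centrality, 1/eccentricity within the component;
* CLC — clustering coefficient, triangles over possible wedges;
* BRC — bridging centrality, bridging coefficient × normalized BC, with
  bridging coefficient (1/deg(v)) / sum over neighbours of 1/deg(u);
* BROC — brokering coefficient, (1 - CLC(v)) · DC(v);
* LAC — local average connectivity: mean degree of v's neighbours inside the
  subgraph they induce;

plus three global ones: average graph distance and diameter over connected
ordered pairs, and network efficiency (mean of 1/d over all ordered pairs,
disconnected pairs contributing zero).

The score value (SV) scheme groups the local parameters into five groups —
G1={DC}, G2={BC}, G3={BRC}, G4={CC, EC}, G5={CLC, BROC, LAC} — and, at each
threshold tau in {10%, 15%, 20%}, awards a node one point per group in which
it ranks inside the top ceil(tau·n) in any member parameter (descending raw
values, competition ranking with boundary-inclusive ties); the maximum SV is
therefore five.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "LOCAL_PARAMETERS",
    "SV_GROUPS",
    "TopologyProfile",
    "ScoreCard",
    "local_parameters",
    "global_parameters",
    "normalize_profile",
    "sv_scores",
    "sv_rank_table",
]

logger = logging.getLogger(__name__)

LOCAL_PARAMETERS = ("DC", "BC", "BRC", "CC", "EC", "CLC", "BROC", "LAC")

SV_GROUPS: dict[int, tuple[str, ...]] = {
    1: ("DC",),
    2: ("BC",),
    3: ("BRC",),
    4: ("CC", "EC"),
    5: ("CLC", "BROC", "LAC"),
}


def _check_simple_undirected(graph: nx.Graph) -> None:
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("topology stage requires a simple undirected graph")
    if any(u == v for u, v in graph.edges):
        raise ValueError("self-loops are not allowed")


@dataclass(frozen=True)
class TopologyProfile:
    """Raw (and optionally normalized) per-node parameters plus global metrics."""

    raw: pd.DataFrame  # nodes × LOCAL_PARAMETERS
    average_distance: float = float("nan")
    diameter: float = float("nan")
    efficiency: float = float("nan")
    normalized: pd.DataFrame | None = field(default=None)

    @property
    def nodes(self) -> list:
        return list(self.raw.index)


def local_parameters(graph: nx.Graph) -> TopologyProfile:
    """Compute the eight local topological parameters for every node."""
    _check_simple_undirected(graph)
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    nodes = list(graph.nodes)
    degree = dict(graph.degree)
    dc = {v: degree[v] / (n - 1) for v in nodes}
    bc = nx.betweenness_centrality(graph, normalized=True)
    cc = nx.closeness_centrality(graph, wf_improved=False)
    clc = nx.clustering(graph)
    # eccentricity per connected component; isolated nodes get EC = 0
    ec: dict = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if len(comp) == 1:
            ec[next(iter(comp))] = 0.0
            continue
        for v, e in nx.eccentricity(sub).items():
            ec[v] = 1.0 / e
    brc, broc, lac = {}, {}, {}
    for v in nodes:
        neigh = list(graph.neighbors(v))
        if degree[v] == 0:
            brc[v] = 0.0
            broc[v] = 0.0
            lac[v] = 0.0
            continue
        inv_sum = sum(1.0 / degree[u] for u in neigh)
        bridging_coeff = (1.0 / degree[v]) / inv_sum
        brc[v] = bridging_coeff * bc[v]
        broc[v] = (1.0 - clc[v]) * dc[v]
        sub = graph.subgraph(neigh)
        lac[v] = 2.0 * sub.number_of_edges() / len(neigh)
    raw = pd.DataFrame(
        {
            "DC": dc,
            "BC": bc,
            "BRC": brc,
            "CC": cc,
            "EC": ec,
            "CLC": clc,
            "BROC": broc,
            "LAC": lac,
        },
        columns=list(LOCAL_PARAMETERS),
    ).loc[nodes]
    return TopologyProfile(raw=raw)


def global_parameters(graph: nx.Graph) -> tuple[float, float, float]:
    """Average distance, diameter (connected ordered pairs) and efficiency."""
    _check_simple_undirected(graph)
    if graph.number_of_edges() < 1:
        raise ValueError("need at least 1 edge")
    n = graph.number_of_nodes()
    total_d = 0.0
    max_d = 0
    n_connected_pairs = 0
    inv_sum = 0.0
    for source, lengths in nx.all_pairs_shortest_path_length(graph):
        for target, d in lengths.items():
            if target == source:
                continue
            total_d += d
            max_d = max(max_d, d)
            n_connected_pairs += 1
            inv_sum += 1.0 / d
    if n_connected_pairs < n * (n - 1):
        logger.info(
            "graph is disconnected: averages over %d of %d ordered pairs",
            n_connected_pairs,
            n * (n - 1),
        )
    average_distance = total_d / n_connected_pairs
    efficiency = inv_sum / (n * (n - 1))
    return average_distance, float(max_d), efficiency


def normalize_profile(profile: TopologyProfile) -> TopologyProfile:
    """Min-max map every parameter onto [-1, 1], keeping the raw values.

    A constant parameter maps to all zeros (logged); the map is affine and
    monotone, so within-parameter rank order never changes.
    """
    norm = {}
    for col in profile.raw.columns:
        vals = profile.raw[col].to_numpy(dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            logger.warning("parameter %s constant; normalized values set to 0", col)
            norm[col] = np.zeros_like(vals)
        else:
            norm[col] = 2.0 * (vals - lo) / (hi - lo) - 1.0
    normalized = pd.DataFrame(norm, index=profile.raw.index, columns=profile.raw.columns)
    return TopologyProfile(
        raw=profile.raw,
        average_distance=profile.average_distance,
        diameter=profile.diameter,
        efficiency=profile.efficiency,
        normalized=normalized,
    )


@dataclass(frozen=True)
class ScoreCard:
    """Per-node SV scores at each ranking threshold."""

    sv: pd.DataFrame  # nodes × thresholds, integer SV in 0..5
    group_hits: dict[float, pd.DataFrame]  # per threshold: nodes × groups bool

    @property
    def thresholds(self) -> list[float]:
        return [float(c) for c in self.sv.columns]


def _top_mask(values: pd.Series, n_top: int) -> pd.Series:
    """Boundary-inclusive top-``n_top`` mask under competition ranking."""
    if len(values) == 0 or n_top < 1:
        return pd.Series(False, index=values.index)
    order = np.sort(values.to_numpy(dtype=float))[::-1]
    cutoff = order[n_top - 1]
    return values >= cutoff


def sv_scores(
    profile: TopologyProfile, thresholds: tuple[float, ...] = (0.10, 0.15, 0.20)
) -> ScoreCard:
    """Group-based score values: +1 per group with a top-ranked member parameter.

    Ranking uses the raw parameter values in descending order; ties at the
    rank boundary are all included (competition ranking), and the cutoff rank
    is ceil(tau · n).
    """
    for tau in thresholds:
        if not 0 < tau < 1:
            raise ValueError(f"threshold {tau} outside (0, 1)")
    n = len(profile.raw)
    sv = pd.DataFrame(index=profile.raw.index)
    group_hits: dict[float, pd.DataFrame] = {}
    for tau in thresholds:
        n_top = int(np.ceil(tau * n))
        hits = pd.DataFrame(index=profile.raw.index)
        for group, params in SV_GROUPS.items():
            mask = pd.Series(False, index=profile.raw.index)
            for p in params:
                mask |= _top_mask(profile.raw[p], n_top)
            hits[f"G{group}"] = mask
        group_hits[float(tau)] = hits
        sv[float(tau)] = hits.sum(axis=1).astype(int)
    return ScoreCard(sv=sv, group_hits=group_hits)


def sv_rank_table(scorecard: ScoreCard) -> pd.DataFrame:
    """Counts of nodes with exactly SV = s (s = 1..5) at each threshold."""
    rows = {}
    for tau in scorecard.thresholds:
        counts = scorecard.sv[tau].value_counts()
        rows[f"{int(round(tau * 100))}%"] = {s: int(counts.get(s, 0)) for s in range(5, 0, -1)}
    table = pd.DataFrame(rows).T
    table.columns.name = "SV"
    return table
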