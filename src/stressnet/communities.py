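"""Phase 3b — overlapping communities of the gene association network.

Two complementary clusterings are provided:

* **k-clique percolation** — a community is the union of all k-cliques that
  can be reached from one another through chains of k-cliques sharing k-1
  nodes.  Percolation runs over the maximal cliques (Bron-Kerbosch with
  pivoting), which yields the identical communities as percolating the
  individual k-cliques.
* **cohesiveness-greedy clustering** — deterministic seeded growth that
  maximizes f(S) = w_in(S) / (w_in(S) + w_bound(S) + penalty·|S|), where
  w_in counts edges inside S and w_bound edges crossing its boundary; grown
  clusters below ``min_size`` are dropped and heavily overlapping clusters
  merged.  This is the densely-connected-cluster refinement used to build
  drug-query gene sets.

A local hypergeometric over-representation test annotates communities
against gene-set collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from stressnet.io import GeneSetCollection

__all__ = [
    "CommunitySet",
    "k_clique_communities",
    "community_size_table",
    "cohesiveness_clusters",
    "over_representation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CommunitySet:
    """A list of (possibly overlapping) node sets with their provenance."""

    k: int | None
    communities: tuple[frozenset, ...]
    provenance: str  # "percolation" | "cohesiveness"

    def __len__(self) -> int:
        return len(self.communities)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.communities]

    def largest(self) -> frozenset:
        if not self.communities:
            raise ValueError("no communities")
        return self.communities[0]


def _sorted_communities(sets: list[frozenset]) -> tuple[frozenset, ...]:
    """Deterministic order: size descending, then lexicographic membership."""
    return tuple(sorted(sets, key=lambda s: (-len(s), sorted(map(str, s)))))


def k_clique_communities(
    graph: nx.Graph, k: int, max_cliques: int = 50_000
) -> CommunitySet:
    """Clique-percolation communities at clique size ``k``.

    Maximal cliques are enumerated with the pivoting Bron-Kerbosch algorithm;
    two k-cliques are adjacent when they share k-1 nodes and a community is a
    connected component of that adjacency relation.  Enumeration aborts with
    a diagnostic when the graph holds more than ``max_cliques`` maximal
    cliques (a safety bound for pathological inputs).
    """
    if k < 3:
        raise ValueError("clique percolation requires k >= 3")
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("requires a simple undirected graph")
    cliques = []
    for i, c in enumerate(nx.find_cliques(graph)):
        if i >= max_cliques:
            raise RuntimeError(
                f"more than {max_cliques} maximal cliques; raise max_cliques to proceed"
            )
        if len(c) >= k:
            cliques.append(frozenset(c))
    # Percolate over maximal cliques: two maximal cliques belong to the same
    # community iff they share >= k-1 nodes (equivalent to percolating all
    # individual k-cliques, since every k-clique sits inside a maximal one).
    membership = {node: [] for node in set().union(*cliques)} if cliques else {}
    for idx, c in enumerate(cliques):
        for node in c:
            membership[node].append(idx)
    overlap = nx.Graph()
    overlap.add_nodes_from(range(len(cliques)))
    for idx, c in enumerate(cliques):
        candidates = {j for node in c for j in membership[node] if j > idx}
        for j in candidates:
            if len(c & cliques[j]) >= k - 1:
                overlap.add_edge(idx, j)
    communities = [
        frozenset(set().union(*(cliques[i] for i in comp)))
        for comp in nx.connected_components(overlap)
    ]
    return CommunitySet(k=k, communities=_sorted_communities(communities), provenance="percolation")


def community_size_table(sets: list[CommunitySet]) -> pd.DataFrame:
    """Per-k multiset of community sizes, formatted as ``size(multiplicity)``.

    Multiplicity 1 is left implicit, e.g. ``56(2), 11, 7(2)``.
    """
    rows = []
    for cs in sets:
        sizes = sorted(cs.sizes(), reverse=True)
        parts = []
        for size in sorted(set(sizes), reverse=True):
            mult = sizes.count(size)
            parts.append(f"{size}({mult})" if mult > 1 else str(size))
        rows.append({"k": cs.k, "sizes": ", ".join(parts), "n_communities": len(cs)})
    return pd.DataFrame(rows).set_index("k")


# ---------------------------------------------------------------------------
# cohesiveness-greedy clustering


def _cohesiveness(graph: nx.Graph, cluster: set, penalty: float) -> float:
    w_in = graph.subgraph(cluster).number_of_edges()
    w_bound = sum(1 for u in cluster for v in graph.neighbors(u) if v not in cluster)
    denom = w_in + w_bound + penalty * len(cluster)
    return w_in / denom if denom > 0 else 0.0


def _grow_cluster(graph: nx.Graph, seed, penalty: float) -> frozenset:
    cluster = {seed}
    score = _cohesiveness(graph, cluster, penalty)
    while True:
        boundary = sorted(
            {v for u in cluster for v in graph.neighbors(u) if v not in cluster}, key=str
        )
        best_move, best_score = None, score
        for v in boundary:
            s = _cohesiveness(graph, cluster | {v}, penalty)
            if s > best_score + 1e-12:
                best_move, best_score = ("add", v), s
        if len(cluster) > 1:
            for v in sorted(cluster, key=str):
                s = _cohesiveness(graph, cluster - {v}, penalty)
                if s > best_score + 1e-12:
                    best_move, best_score = ("remove", v), s
        if best_move is None:
            return frozenset(cluster)
        op, v = best_move
        cluster.add(v) if op == "add" else cluster.remove(v)
        score = best_score


def cohesiveness_clusters(
    graph: nx.Graph,
    min_size: int = 3,
    penalty: float = 2.0,
    overlap_threshold: float = 0.8,
) -> CommunitySet:
    """Greedy cohesiveness clustering of a simple graph.

    Seeds are the nodes in descending degree order (ties broken by label);
    each unvisited seed grows a cluster by best-improvement add/remove moves
    on f(S) = w_in/(w_in + w_bound + penalty·|S|).  Clusters smaller than
    ``min_size`` are discarded, and clusters whose overlap score
    |A∩B|²/(|A||B|) exceeds ``overlap_threshold`` are merged.  The procedure
    is fully deterministic.
    """
    if min_size < 2:
        raise ValueError("min_size must be at least 2")
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("requires a simple undirected graph")
    seeds = sorted(graph.nodes, key=lambda v: (-graph.degree(v), str(v)))
    covered: set = set()
    clusters: list[frozenset] = []
    for seed in seeds:
        if seed in covered:
            continue
        cluster = _grow_cluster(graph, seed, penalty)
        covered |= cluster
        if len(cluster) >= min_size:
            clusters.append(cluster)
    # merge heavily overlapping clusters
    merged = True
    while merged:
        merged = False
        for i, j in combinations(range(len(clusters)), 2):
            a, b = clusters[i], clusters[j]
            ov = len(a & b) ** 2 / (len(a) * len(b))
            if ov > overlap_threshold:
                clusters[i] = a | b
                del clusters[j]
                merged = True
                break
    return CommunitySet(k=None, communities=_sorted_communities(clusters), provenance="cohesiveness")


# ---------------------------------------------------------------------------
# over-representation analysis


def over_representation(
    community: set[str] | frozenset[str],
    gene_sets: GeneSetCollection,
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a community in gene sets.

    Every gene set is first intersected with the universe; the community must
    be contained in the universe.  Returns one row per set with the overlap
    count, enrichment tail p-value and Benjamini-Hochberg adjusted p.
    """
    universe = set(universe)
    community = set(community)
    if not community <= universe:
        raise ValueError(f"community genes outside universe: {sorted(community - universe)[:5]}")
    if not community & universe:
        raise ValueError("empty intersection of community and universe")
    M = len(universe)
    N = len(community)
    rows = []
    for name in gene_sets.names():
        members = set(gene_sets[name]) & universe
        n = len(members)
        k = len(members & community)
        # P(X >= k) for X ~ Hypergeom(M, n, N); k = 0 gives p = 1.
        p = float(hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append({"set": name, "set_size": n, "overlap": k, "p": min(p, 1.0)})
    table = pd.DataFrame(rows).set_index("set")
    table["p_adjusted"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table.sort_values(["p", "set_size"])
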