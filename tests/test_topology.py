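from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressnet import topology as topo


# ---------------------------------------------------------------------------
# brute-force oracles (path enumeration / literal definitions)


def _bfs_distances(graph, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_betweenness(graph):
    """Normalized betweenness from explicit shortest-path enumeration."""
    n = graph.number_of_nodes()
    bc = {v: 0.0 for v in graph.nodes}
    for s, t in combinations(graph.nodes, 2):
        if not nx.has_path(graph, s, t):
            continue
        paths = list(nx.all_shortest_paths(graph, s, t))
        for v in graph.nodes:
            if v in (s, t):
                continue
            frac = sum(1 for p in paths if v in p) / len(paths)
            bc[v] += frac
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return {v: bc[v] * scale for v in bc}


def brute_closeness(graph):
    out = {}
    for v in graph.nodes:
        dist = _bfs_distances(graph, v)
        others = {u: d for u, d in dist.items() if u != v}
        out[v] = len(others) / sum(others.values()) if others else 0.0
    return out


def brute_eccentricity_centrality(graph):
    out = {}
    for v in graph.nodes:
        dist = _bfs_distances(graph, v)
        ecc = max(d for d in dist.values())
        out[v] = 1.0 / ecc if ecc > 0 else 0.0
    return out


def brute_clustering(graph):
    out = {}
    for v in graph.nodes:
        neigh = list(graph.neighbors(v))
        k = len(neigh)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(neigh, 2) if graph.has_edge(a, b))
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def random_graph(seed, n_max=30):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.1, 0.5))
    return nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))


@settings(deadline=None, max_examples=12)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_centralities_match_brute_force(seed):
    """BC, CC, EC, CLC agree exactly with path-enumeration oracles."""
    graph = random_graph(seed)
    if graph.number_of_nodes() < 2:
        return
    profile = topo.local_parameters(graph).raw
    for v, ref in brute_betweenness(graph).items():
        assert profile.loc[v, "BC"] == pytest.approx(ref, abs=1e-10)
    for v, ref in brute_closeness(graph).items():
        assert profile.loc[v, "CC"] == pytest.approx(ref, abs=1e-10)
    for v, ref in brute_eccentricity_centrality(graph).items():
        assert profile.loc[v, "EC"] == pytest.approx(ref, abs=1e-10)
    for v, ref in brute_clustering(graph).items():
        assert profile.loc[v, "CLC"] == pytest.approx(ref, abs=1e-10)


def test_path_graph_values():
    g = nx.path_graph(["a", "b", "c"])
    raw = topo.local_parameters(g).raw
    assert raw.loc["b", "BC"] == pytest.approx(1.0)
    assert raw.loc["a", "BC"] == 0.0
    assert raw.loc["b", "DC"] == pytest.approx(1.0)
    avg_d, diam, eff = topo.global_parameters(g)
    assert avg_d == pytest.approx(4.0 / 3.0)
    assert diam == 2


def test_triangle_and_complete_graph():
    raw = topo.local_parameters(nx.complete_graph(3)).raw
    assert (raw["CLC"] == 1.0).all()
    assert (raw["LAC"] == 1.0).all()
    avg_d, diam, eff = topo.global_parameters(nx.complete_graph(4))
    assert eff == pytest.approx(1.0)
    assert diam == 1


def test_star_graph_conventions():
    g = nx.star_graph(4)  # center 0, leaves 1..4
    raw = topo.local_parameters(g).raw
    assert raw.loc[0, "LAC"] == 0.0  # leaves mutually disconnected
    assert (raw.loc[1:, "CLC"] == 0.0).all()  # degree-1 nodes: CLC -> 0 by convention
    assert raw.loc[0, "DC"] == pytest.approx(1.0)


def test_two_disjoint_edges_efficiency():
    g = nx.Graph([("a", "b"), ("c", "d")])
    avg_d, diam, eff = topo.global_parameters(g)
    assert eff == pytest.approx(1.0 / 3.0)  # 4 ordered pairs at distance 1 of 12
    assert diam == 1


def test_bridging_centrality_definition():
    """BRC equals the literal bridging-coefficient × normalized-BC product."""
    g = random_graph(99)
    raw = topo.local_parameters(g).raw
    for v in g.nodes:
        deg = g.degree(v)
        if deg == 0:
            assert raw.loc[v, "BRC"] == 0.0
            continue
        bcoef = (1.0 / deg) / sum(1.0 / g.degree(u) for u in g.neighbors(v))
        assert raw.loc[v, "BRC"] == pytest.approx(bcoef * raw.loc[v, "BC"], abs=1e-12)


# ---------------------------------------------------------------------------
# normalization


def test_normalize_affine_endpoints():
    import pandas as pd

    profile = topo.TopologyProfile(
        raw=pd.DataFrame({c: [0.0, 5.0, 10.0] for c in topo.LOCAL_PARAMETERS}, index=list("xyz"))
    )
    norm = topo.normalize_profile(profile).normalized
    np.testing.assert_allclose(norm["DC"], [-1.0, 0.0, 1.0])


def test_normalize_constant_parameter_and_rank_preservation():
    import pandas as pd

    rng = np.random.default_rng(7)
    raw = pd.DataFrame(
        {c: rng.normal(size=10) for c in topo.LOCAL_PARAMETERS}, index=range(10)
    )
    raw["CLC"] = 0.5
    profile = topo.normalize_profile(topo.TopologyProfile(raw=raw))
    assert (profile.normalized["CLC"] == 0.0).all()
    for c in topo.LOCAL_PARAMETERS:
        if c == "CLC":
            continue
        assert np.array_equal(
            np.argsort(raw[c].to_numpy()), np.argsort(profile.normalized[c].to_numpy())
        )
    assert profile.normalized.to_numpy().min() >= -1.0
    assert profile.normalized.to_numpy().max() <= 1.0


# ---------------------------------------------------------------------------
# SV scores


def test_sv_group_structure():
    """A node leading one parameter of every group scores 5; CC+EC only scores 1."""
    import pandas as pd

    rng = np.random.default_rng(0)
    raw = pd.DataFrame(
        rng.uniform(0.0, 0.5, size=(20, len(topo.LOCAL_PARAMETERS))),
        index=[f"n{i}" for i in range(20)],
        columns=list(topo.LOCAL_PARAMETERS),
    )
    raw.loc["n0"] = 0.0
    raw.loc["n1"] = 0.0
    raw.loc["n0", ["DC", "BC", "BRC", "CC", "CLC"]] = 1.0  # one hit per group
    raw.loc["n1", ["CC", "EC"]] = 2.0  # two hits in group 4 count once
    card = topo.sv_scores(topo.TopologyProfile(raw=raw), thresholds=(0.10,))
    assert card.sv.loc["n0", 0.10] == 5
    assert card.sv.loc["n1", 0.10] == 1


@settings(deadline=None, max_examples=10)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_sv_monotone_in_threshold(seed):
    graph = random_graph(seed, n_max=25)
    if graph.number_of_nodes() < 2:
        return
    card = topo.sv_scores(topo.local_parameters(graph), thresholds=(0.10, 0.15, 0.20))
    sv = card.sv
    assert (sv[0.15] >= sv[0.10]).all()
    assert (sv[0.20] >= sv[0.15]).all()


def test_sv_table_permutation_invariance():
    graph = random_graph(5)
    profile = topo.local_parameters(graph)
    table = topo.sv_rank_table(topo.sv_scores(profile))
    relabeled = nx.relabel_nodes(graph, {v: f"x{v}" for v in graph.nodes})
    table2 = topo.sv_rank_table(topo.sv_scores(topo.local_parameters(relabeled)))
    assert table.equals(table2)


def test_hub_attains_high_sv():
    """A planted hub dominating degree/betweenness scores SV >= 3 at 10%."""
    g = nx.star_graph(20)
    extra = nx.path_graph(range(21, 30))
    g = nx.compose(g, extra)
    g.add_edge(1, 21)
    card = topo.sv_scores(topo.local_parameters(g), thresholds=(0.10,))
    assert card.sv.loc[0, 0.10] >= 3


def test_sv_rank_table_shape_and_degenerate_ties():
    import pandas as pd

    raw = pd.DataFrame(1.0, index=[f"n{i}" for i in range(8)], columns=list(topo.LOCAL_PARAMETERS))
    card = topo.sv_scores(topo.TopologyProfile(raw=raw), thresholds=(0.10,))
    table = topo.sv_rank_table(card)
    # all nodes tie everywhere -> everyone is top-ranked in every group
    assert table.loc["10%", 5] == 8
    assert table.loc["10%", [4, 3, 2, 1]].sum() == 0
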