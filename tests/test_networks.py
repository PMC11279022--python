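"""cooccurrence_networks: correlations, thresholding, modules, topology."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from leafendo.networks import (
    CoNetwork,
    build_network,
    greedy_modules,
    module_summary,
    spearman_matrix,
    topology_metrics,
    write_graphml,
)
from leafendo.sensitive import tmm_normalize

from conftest import make_table


def _df(x, taxa=None):
    x = np.asarray(x, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(x.shape[0])]
    return pd.DataFrame(x, index=taxa, columns=[f"s{j}" for j in range(x.shape[1])])


# ---------------------------------------------------------------------------
# spearman_matrix
# ---------------------------------------------------------------------------

def test_spearman_perfect_monotone():
    x = np.arange(1.0, 9.0)
    df = _df(np.vstack([x, x**2, -x]))
    r, p = spearman_matrix(df, within_kingdom=False)
    assert r.loc["t0", "t1"] == pytest.approx(1.0)
    assert r.loc["t0", "t2"] == pytest.approx(-1.0)
    assert p.loc["t0", "t1"] < 1e-6


def test_spearman_matches_scipy_with_ties():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 5, size=(6, 12)).astype(float)
    x[:, 0] += 1  # avoid constant rows
    df = _df(x)
    r, p = spearman_matrix(df, within_kingdom=False)
    for i, j in itertools.combinations(range(6), 2):
        ref_r, ref_p = stats.spearmanr(x[i], x[j])
        assert r.iloc[i, j] == pytest.approx(ref_r, abs=1e-12)
        assert p.iloc[i, j] == pytest.approx(ref_p, abs=1e-9)


def test_spearman_constant_taxon_nan():
    df = _df([[1, 2, 3, 4, 5], [7, 7, 7, 7, 7]])
    r, p = spearman_matrix(df, within_kingdom=False)
    assert np.isnan(r.loc["t0", "t1"]) and np.isnan(p.loc["t0", "t1"])


def test_spearman_kingdom_masking():
    x = np.tile(np.arange(1.0, 7.0), (3, 1))
    x += np.arange(3)[:, None] * 0.1
    df = _df(x)
    kd = {"t0": "bacteria", "t1": "bacteria", "t2": "fungi"}
    r, _ = spearman_matrix(df, kingdoms=kd, within_kingdom=True)
    assert r.loc["t0", "t1"] == pytest.approx(1.0)
    assert np.isnan(r.loc["t0", "t2"])
    r2, _ = spearman_matrix(df, kingdoms=kd, within_kingdom=False)
    assert r2.loc["t0", "t2"] == pytest.approx(1.0)


def test_spearman_needs_five_samples():
    with pytest.raises(ValueError, match=">= 5 samples"):
        spearman_matrix(_df([[1, 2, 3, 4], [4, 3, 2, 1]]), within_kingdom=False)


# ---------------------------------------------------------------------------
# build_network
# ---------------------------------------------------------------------------

def _rp(r_vals):
    n = len(r_vals)
    r = pd.DataFrame(r_vals, index=[f"t{i}" for i in range(n)],
                     columns=[f"t{i}" for i in range(n)], dtype=float)
    p = r.copy()
    p[:] = 1e-6
    np.fill_diagonal(p.values, 0.0)
    return r, p


def test_build_network_strict_thresholds():
    r, p = _rp([[1.0, 0.8, 0.6], [0.8, 1.0, -0.9], [0.6, -0.9, 1.0]])
    net = build_network(r, p, r_min=0.6, p_max=1e-3)
    # r = 0.6 is NOT > 0.6; r = -0.9 excluded by positivity
    assert set(net.graph.edges) == {("t0", "t1")}
    assert net.graph["t0"]["t1"]["r"] == pytest.approx(0.8)


def test_build_network_negative_edges_when_allowed():
    # the threshold applies to signed r: a negative edge needs a negative
    # r_min and positive_only=False
    r, p = _rp([[1.0, 0.8, 0.6], [0.8, 1.0, -0.9], [0.6, -0.9, 1.0]])
    net = build_network(r, p, r_min=0.6, p_max=1e-3, positive_only=False)
    assert ("t1", "t2") not in net.graph.edges
    net2 = build_network(r, p, r_min=-0.95, p_max=1e-3, positive_only=False)
    assert ("t1", "t2") in net2.graph.edges


def test_build_network_p_threshold_excludes():
    r, p = _rp([[1.0, 0.9], [0.9, 1.0]])
    p.loc["t0", "t1"] = p.loc["t1", "t0"] = 0.05
    net = build_network(r, p, r_min=0.6, p_max=0.01)
    assert net.n_edges == 0


def test_build_network_monotone_in_threshold():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((20, 15))
    df = _df(x)
    r, p = spearman_matrix(df, within_kingdom=False)
    loose = build_network(r, p, r_min=0.3, p_max=0.2)
    tight = build_network(r, p, r_min=0.6, p_max=0.05)
    tight_edges = {frozenset(e) for e in tight.graph.edges}
    loose_edges = {frozenset(e) for e in loose.graph.edges}
    assert tight_edges <= loose_edges


def test_build_network_validation():
    r, p = _rp([[1.0, 0.9], [0.9, 1.0]])
    with pytest.raises(ValueError, match="p_max"):
        build_network(r, p, r_min=0.5, p_max=1.5)


def test_correlated_block_forms_dense_subgraph(small_dataset):
    table, _, truth = small_dataset
    norm = tmm_normalize(table)
    r, p = spearman_matrix(norm, within_kingdom=False)
    net = build_network(r, p, r_min=0.5, p_max=0.01)
    blocks = {}
    for taxon, b in truth.true_blocks.items():
        blocks.setdefault(b, []).append(taxon)
    g = net.graph
    all_taxa = list(table.taxon_ids)
    background = 2 * g.number_of_edges() / (len(all_taxa) * (len(all_taxa) - 1))
    for members in blocks.values():
        pairs = list(itertools.combinations(members, 2))
        got = sum(g.has_edge(u, v) for u, v in pairs) / len(pairs)
        # block pairs must be far denser than the background edge density
        assert got > 0.3
        assert got > 5 * background


# ---------------------------------------------------------------------------
# modules / modularity
# ---------------------------------------------------------------------------

def _net_from_edges(edges):
    g = nx.Graph()
    g.add_edges_from((u, v, {"r": 1.0, "p": 0.0}) for u, v in edges)
    return CoNetwork(graph=g, r_min=0.0, p_max=1.0)


def test_two_triangles_modularity_half():
    # two disjoint triangles: optimal partition has Q exactly 0.5
    edges = [("a", "b"), ("b", "c"), ("a", "c"),
             ("x", "y"), ("y", "z"), ("x", "z")]
    net = greedy_modules(_net_from_edges(edges))
    assert net.modularity == pytest.approx(0.5)
    mods = net.modules
    assert mods["a"] == mods["b"] == mods["c"]
    assert mods["x"] == mods["y"] == mods["z"]
    assert mods["a"] != mods["x"]


def test_edgeless_network_singletons():
    g = nx.Graph()
    g.add_nodes_from(["a", "b"])
    net = greedy_modules(CoNetwork(graph=g, r_min=0.0, p_max=1.0))
    assert net.modularity == 0.0
    assert len(set(net.modules.values())) == 2


def test_two_block_recovery_ari():
    # stochastic block model: dense blocks, sparse cross edges; greedy
    # modularity should recover the planted split (mean ARI >= 0.9)
    from sklearn.metrics import adjusted_rand_score

    aris = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n = 15
        edges = []
        for block, offset in ((0, 0), (1, n)):
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.5:
                    edges.append((f"n{offset + i}", f"n{offset + j}"))
        for i in range(n):
            for j in range(n):
                if rng.random() < 0.05:
                    edges.append((f"n{i}", f"n{n + j}"))
        net = greedy_modules(_net_from_edges(edges))
        mods = net.modules
        nodes = sorted(mods)
        truth = [0 if int(x[1:]) < n else 1 for x in nodes]
        aris.append(adjusted_rand_score(truth, [mods[x] for x in nodes]))
    assert np.mean(aris) >= 0.9


def test_greedy_modules_deterministic():
    edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("e", "f")]
    m1 = greedy_modules(_net_from_edges(edges)).modules
    m2 = greedy_modules(_net_from_edges(list(reversed(edges)))).modules
    assert m1 == m2


# ---------------------------------------------------------------------------
# topology metrics
# ---------------------------------------------------------------------------

def test_star_graph_metrics():
    # star K_{1,5}: centre betweenness 1.0, leaves 0 -> mean 1/6;
    # degree assortativity of any star is -1
    edges = [("c", f"l{i}") for i in range(5)]
    net = _net_from_edges(edges)
    m = topology_metrics(net)
    assert m["n_nodes"] == 6 and m["n_edges"] == 5
    assert m["mean_betweenness"] == pytest.approx(1 / 6)
    assert m["degree_assortativity"] == pytest.approx(-1.0)


def test_complete_graph_zero_betweenness_regular_assortativity_none():
    edges = list(itertools.combinations("abcd", 2))
    m = topology_metrics(_net_from_edges(edges))
    assert m["mean_betweenness"] == pytest.approx(0.0)
    assert m["degree_assortativity"] is None  # regular graph: undefined


def test_betweenness_matches_naive_enumeration():
    # brute-force all-pairs shortest-path counting on a 9-node graph
    rng = np.random.default_rng(5)
    nodes = [f"n{i}" for i in range(9)]
    edges = [(u, v) for u, v in itertools.combinations(nodes, 2) if rng.random() < 0.35]
    g = nx.Graph(edges)
    g.add_nodes_from(nodes)
    net = CoNetwork(graph=g, r_min=0.0, p_max=1.0)
    m = topology_metrics(net)

    def naive_betweenness(graph):
        bc = dict.fromkeys(graph, 0.0)
        for s, t in itertools.combinations(graph.nodes, 2):
            try:
                paths = list(nx.all_shortest_paths(graph, s, t))
            except nx.NetworkXNoPath:
                continue
            for v in graph.nodes:
                if v in (s, t):
                    continue
                frac = sum(v in pth for pth in paths) / len(paths)
                bc[v] += frac
        n = graph.number_of_nodes()
        scale = (n - 1) * (n - 2) / 2
        return {v: val / scale for v, val in bc.items()}

    ref = naive_betweenness(g)
    assert m["mean_betweenness"] == pytest.approx(np.mean(list(ref.values())), abs=1e-12)


def test_empty_graph_metrics_none():
    m = topology_metrics(CoNetwork(graph=nx.Graph(), r_min=0.0, p_max=1.0))
    assert m["n_nodes"] == 0
    assert m["mean_betweenness"] is None


# ---------------------------------------------------------------------------
# module_summary / graphml
# ---------------------------------------------------------------------------

def test_module_summary_and_graphml_round_trip(tmp_path, small_dataset):
    table, groups, _ = small_dataset
    norm = tmm_normalize(table)
    r, p = spearman_matrix(norm, within_kingdom=False)
    net = greedy_modules(build_network(r, p, r_min=0.5, p_max=0.01))
    summ = module_summary(net, norm, groups=groups)
    assert (summ["n_members"] >= 1).all()
    assert summ["n_members"].sum() == net.n_nodes
    assert {"cum_cpm_mean_HL", "cum_cpm_mean_NL"} <= set(summ.columns)

    path = tmp_path / "net.graphml"
    write_graphml(net, path)
    back = nx.read_graphml(path)
    assert back.number_of_nodes() == net.n_nodes
    assert back.number_of_edges() == net.n_edges
    some = next(iter(back.nodes))
    assert back.nodes[some]["module"] == net.modules[some]


def test_module_summary_requires_modules(small_dataset):
    table, _, _ = small_dataset
    norm = tmm_normalize(table)
    r, p = spearman_matrix(norm, within_kingdom=False)
    net = build_network(r, p, r_min=0.5, p_max=0.01)
    with pytest.raises(ValueError, match="greedy_modules"):
        module_summary(net, norm)


def test_assortativity_matches_direct_correlation():
    # degree assortativity equals the Pearson correlation of end-point
    # degrees over the edge list (both orientations)
    rng = np.random.default_rng(7)
    nodes = [f"n{i}" for i in range(20)]
    edges = [(u, v) for u, v in itertools.combinations(nodes, 2) if rng.random() < 0.2]
    g = nx.Graph(edges)
    m = topology_metrics(CoNetwork(graph=g, r_min=0.0, p_max=1.0))
    deg = dict(g.degree)
    xs, ys = [], []
    for u, v in g.edges:
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    ref = np.corrcoef(xs, ys)[0, 1]
    assert m["degree_assortativity"] == pytest.approx(ref, abs=1e-9)
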