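"""Graph metrics against hand computations and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from graspsource import netmetrics as nm
from graspsource.connectivity import PLVTensor, threshold_graph


# ---------------------------------------------------------------------------
# brute-force oracles (independent of networkx algorithms)


def brute_degree_density(g):
    n = g.number_of_nodes()
    de = np.mean([
        sum(g[u][v].get("weight", 1.0) for v in g[u]) for u in g.nodes
    ]) if n else 0.0
    ds = g.number_of_edges() / (n * (n - 1) / 2) if n > 1 else 0.0
    return float(de), float(ds)


def brute_clustering(g):
    """Weighted geometric-mean triangle clustering, weights scaled by max."""
    if g.number_of_edges() == 0:
        return 0.0
    wmax = max(d.get("weight", 1.0) for _, _, d in g.edges(data=True))

    def w(u, v):
        return g[u][v].get("weight", 1.0) / wmax if g.has_edge(u, v) else 0.0

    ccs = []
    for u in g.nodes:
        nbrs = list(g[u])
        k = len(nbrs)
        if k < 2:
            ccs.append(0.0)
            continue
        tri = sum(
            (w(u, a) * w(u, b) * w(a, b)) ** (1 / 3)
            for a, b in itertools.combinations(nbrs, 2)
        )
        ccs.append(2 * tri / (k * (k - 1)))
    return float(np.mean(ccs))


def brute_cpl(g):
    """Floyd-Warshall over 1/weight distances; mean over connected pairs."""
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v, dat in g.edges(data=True):
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0 / dat.get("weight", 1.0)
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    iu = np.triu_indices(n, 1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    return float(finite.mean()) if finite.size else float("nan")


def weighted_graph(edges):
    g = nx.Graph()
    g.add_weighted_edges_from(edges)
    return g


class TestDegreeDensity:
    def test_unit_triangle(self):
        g = weighted_graph([(0, 1, 1), (1, 2, 1), (0, 2, 1)])
        assert nm.degree_density(g) == (2.0, 1.0)

    def test_empty_graph_on_24_nodes(self):
        g = nx.empty_graph(24)
        assert nm.degree_density(g) == (0.0, 0.0)

    def test_star_with_weight_0p8(self):
        g = weighted_graph([(0, i, 0.8) for i in range(1, 5)])
        de, ds = nm.degree_density(g)
        assert de == pytest.approx((4 * 0.8 + 4 * 0.8) / 5)  # 1.28
        assert ds == pytest.approx(4 / 10)

    def test_adding_edge_never_decreases(self):
        g = weighted_graph([(0, 1, 0.7), (1, 2, 0.9)])
        g.add_nodes_from(range(5))
        de0, ds0 = nm.degree_density(g)
        g.add_edge(3, 4, weight=0.8)
        de1, ds1 = nm.degree_density(g)
        assert de1 >= de0 and ds1 >= ds0


class TestClustering:
    def test_complete_triangle(self):
        g = weighted_graph([(0, 1, 1), (1, 2, 1), (0, 2, 1)])
        assert nm.clustering(g) == pytest.approx(1.0)

    def test_path_graph_has_no_triangles(self):
        g = weighted_graph([(0, 1, 1), (1, 2, 1)])
        assert nm.clustering(g) == 0.0

    def test_4_clique_with_one_light_edge_matches_enumeration(self):
        edges = [(0, 1, 1), (0, 2, 1), (0, 3, 1), (1, 2, 1), (1, 3, 1), (2, 3, 0.5)]
        g = weighted_graph(edges)
        assert nm.clustering(g) == pytest.approx(brute_clustering(g), abs=1e-12)


class TestCharPathLength:
    def test_unit_path_graph(self):
        g = weighted_graph([(0, 1, 1), (1, 2, 1)])
        assert nm.char_path_length(g) == pytest.approx(4 / 3)

    def test_complete_unit_graph(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 1.0, "weight")
        assert nm.char_path_length(g) == pytest.approx(1.0)

    def test_random_24_node_graph_matches_floyd_warshall(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(24, 0.2, seed=3)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.3, 1.0))
        assert nm.char_path_length(g) == pytest.approx(brute_cpl(g), abs=1e-9)

    def test_edgeless_graph_is_nan(self):
        assert np.isnan(nm.char_path_length(nx.empty_graph(5)))


class TestModularity:
    def test_two_disconnected_triangles(self):
        g = weighted_graph(
            [(0, 1, 1), (1, 2, 1), (0, 2, 1), (3, 4, 1), (4, 5, 1), (3, 5, 1)]
        )
        q, modules = nm.modularity_partition(g, seed=1)
        assert q == pytest.approx(0.5)
        assert len(set(modules.values())) == 2

    def test_trivial_partition_scores_zero(self):
        g = nx.complete_graph(8)
        nx.set_edge_attributes(g, 1.0, "weight")
        from networkx.algorithms.community import modularity

        assert modularity(g, [set(g.nodes)], weight="weight") == pytest.approx(0.0)

    def test_planted_six_module_recovery(self):
        g = nx.Graph()
        for m in range(6):
            nodes = [4 * m + i for i in range(4)]
            for a, b in itertools.combinations(nodes, 2):
                g.add_edge(a, b, weight=0.9)
        q, modules = nm.modularity_partition(g, seed=2)
        assert len(set(modules.values())) == 6
        assert q > 0.7

    def test_edgeless_graph_undefined(self):
        q, modules = nm.modularity_partition(nx.empty_graph(4))
        assert np.isnan(q)
        assert len(set(modules.values())) == 4


class TestOracleEquivalence:
    def test_random_weighted_graphs_match_brute_force(self):
        rng = np.random.default_rng(7)
        for trial in range(30):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 16)))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.2, 1.0))
            de, ds = nm.degree_density(g)
            bde, bds = brute_degree_density(g)
            assert de == pytest.approx(bde, abs=1e-12)
            assert ds == pytest.approx(bds, abs=1e-12)
            assert nm.clustering(g) == pytest.approx(brute_clustering(g), abs=1e-9)
            cpl, bcpl = nm.char_path_length(g), brute_cpl(g)
            if np.isnan(bcpl):
                assert np.isnan(cpl)
            else:
                assert cpl == pytest.approx(bcpl, abs=1e-9)


class TestMetricsTimecourse:
    def make_tensor(self, values, centers):
        return PLVTensor(
            values=values,
            window_centers=np.asarray(centers, float),
            window_s=1.0,
            step_s=0.1,
        )

    def test_all_ones_has_full_density_everywhere(self):
        v = np.ones((41, 24, 24))
        tensor = self.make_tensor(v, -1.5 + 0.1 * np.arange(41))
        df = nm.metrics_timecourse(tensor, "palmar", times=(-1.0, 0.0, 1.4))
        assert (df["DS"] == 1.0).all()
        assert len(df) == 3

    def test_time_outside_coverage_rejected(self):
        v = np.ones((5, 24, 24))
        tensor = self.make_tensor(v, [0.0, 0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="coverage"):
            nm.metrics_timecourse(tensor, "palmar", times=(2.0,))

    def test_rising_within_module_coupling_raises_cc_and_lowers_cpl(self):
        """As within-module PLV strengthens over windows, clustering should
        increase and characteristic path length decrease."""
        rng = np.random.default_rng(8)
        centers = np.array([-1.0, 0.0, 1.4])
        values = np.zeros((3, 24, 24))
        u = rng.uniform(0, 1, (24, 24))
        u = 0.5 * (u + u.T)
        for w, gain in enumerate([0.16, 0.22, 0.35]):
            m = np.clip(0.55 + gain * u, 0, 1)
            np.fill_diagonal(m, 1.0)
            values[w] = m
        tensor = self.make_tensor(values, centers)
        df = nm.metrics_timecourse(tensor, "palmar", times=tuple(centers))
        cc = df["CC"].to_numpy()
        cpl = df["CPL"].to_numpy()
        assert cc[0] < cc[1] < cc[2]
        assert cpl[0] > cpl[1] > cpl[2]
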