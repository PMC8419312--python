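"""Graph metrics against hand-derived values and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funconn import (
    BinaryGraph,
    characteristic_path_length,
    clustering_coefficient,
    metric_curves,
    nodal_centrality,
    rewire_null,
    small_world_index,
)
from ._bruteforce import (
    bf_betweenness,
    bf_clustering,
    bf_degree_centrality,
    bf_path_length,
    random_graph,
)


def graph_from_edges(n, edges, density=0.5):
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return BinaryGraph(adjacency=adj, density=density)


def complete_graph(n):
    adj = ~np.eye(n, dtype=bool)
    return BinaryGraph(adjacency=adj, density=1.0)


class TestClustering:
    def test_complete_graph_is_fully_clustered(self):
        assert clustering_coefficient(complete_graph(4)) == pytest.approx(1.0)

    def test_triangle_free_cycle_has_zero_clustering(self):
        g = graph_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])
        assert clustering_coefficient(g) == 0.0

    def test_triangle_with_pendant_edge(self):
        # nodes 0,1,2 form a triangle; 3 hangs off node 2
        g = graph_from_edges(4, [(0, 1), (1, 2), (0, 2), (2, 3)])
        assert clustering_coefficient(g) == pytest.approx(7 / 12)

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValueError):
            clustering_coefficient(graph_from_edges(2, [(0, 1)]))


class TestPathLength:
    def test_complete_graphs_have_unit_path_length(self):
        for n in (2, 3, 6):
            lp, frac = characteristic_path_length(complete_graph(n))
            assert lp == pytest.approx(1.0)
            assert frac == 0.0

    def test_path_graph_mean_distance(self):
        g = graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        lp, frac = characteristic_path_length(g)
        assert lp == pytest.approx(5 / 3)
        assert frac == 0.0

    def test_disconnected_components_report_unreachable_fraction(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        lp, frac = characteristic_path_length(g)
        assert lp == pytest.approx(1.0)
        assert frac == pytest.approx(2 / 3)

    def test_edgeless_graph_rejected(self):
        adj = np.zeros((4, 4), dtype=bool)
        g = BinaryGraph(adjacency=adj, density=0.01)
        with pytest.raises(ValueError, match="no reachable"):
            characteristic_path_length(g)


class TestRewiring:
    def test_degree_sequence_and_edge_count_preserved(self, rng):
        for trial in range(20):
            adj = random_graph(30, 0.2, rng)
            if adj.sum() < 4:
                continue
            g = BinaryGraph(adjacency=adj, density=0.2)
            null = rewire_null(g, n_swap_per_edge=10, seed=trial)
            assert null.n_edges == g.n_edges
            assert np.array_equal(null.degrees, g.degrees)
            assert not np.any(np.diag(null.adjacency))

    def test_complete_graph_has_no_legal_swaps(self):
        g = complete_graph(6)
        null = rewire_null(g, n_swap_per_edge=50, seed=3)
        assert np.array_equal(null.adjacency, g.adjacency)

    def test_deterministic_given_seed(self, rng):
        g = BinaryGraph(adjacency=random_graph(25, 0.3, rng), density=0.3)
        a = rewire_null(g, seed=11).adjacency
        b = rewire_null(g, seed=11).adjacency
        c = rewire_null(g, seed=12).adjacency
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_rewiring_destroys_lattice_clustering(self):
        import networkx as nx

        src = nx.watts_strogatz_graph(100, 10, 0.05, seed=0)
        adj = nx.to_numpy_array(src) > 0
        g = BinaryGraph(adjacency=adj, density=0.1)
        cp0 = clustering_coefficient(g)
        null_cps = [
            clustering_coefficient(rewire_null(g, n_swap_per_edge=10, seed=s))
            for s in range(50)
        ]
        assert np.mean(null_cps) < cp0


class TestSmallWorldIndex:
    def test_complete_graph_sigma_is_exactly_one(self):
        r = small_world_index(complete_graph(8), n_nulls=5, seed=0)
        assert r.gamma == 1.0 and r.lam == 1.0 and r.sigma == 1.0

    def test_erdos_renyi_sigma_near_one(self):
        import networkx as nx

        src = nx.gnm_random_graph(100, 990, seed=4)
        adj = nx.to_numpy_array(src) > 0
        g = BinaryGraph(adjacency=adj, density=0.2)
        r = small_world_index(g, n_nulls=100, seed=5)
        assert 0.9 <= r.sigma <= 1.1

    def test_watts_strogatz_sigma_above_one(self):
        import networkx as nx

        src = nx.watts_strogatz_graph(100, 10, 0.05, seed=0)
        adj = nx.to_numpy_array(src) > 0
        g = BinaryGraph(adjacency=adj, density=adj.sum() / (100 * 99))
        r = small_world_index(g, n_nulls=50, seed=6)
        assert r.sigma > 1.0
        assert r.sigma * r.lam == pytest.approx(r.gamma, rel=1e-12)

    def test_density_one_limit_is_degenerate_small_world(self):
        r = small_world_index(complete_graph(12), n_nulls=3, seed=1)
        assert r.cp == pytest.approx(1.0)
        assert r.lp == pytest.approx(1.0)
        assert r.sigma == pytest.approx(1.0)


class TestCentrality:
    def test_star_graph_degree_centrality(self):
        g = graph_from_edges(6, [(0, i) for i in range(1, 6)])
        c = nodal_centrality(g, "degree")
        assert c[0] == pytest.approx(1.0)
        assert np.allclose(c[1:], 0.2)

    def test_cycle_graph_uniform_centrality(self):
        n = 8
        g = graph_from_edges(n, [(i, (i + 1) % n) for i in range(n)])
        assert np.allclose(nodal_centrality(g, "degree"), 2 / (n - 1))

    def test_kite_betweenness_matches_path_enumeration(self):
        # 5-node kite: diamond 0-1-2-3 (with 1-2 chord) plus tail 3-4
        g = graph_from_edges(
            5, [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3), (3, 4)]
        )
        got = nodal_centrality(g, "betweenness")
        expected = bf_betweenness(g.adjacency)
        assert np.allclose(got, expected, atol=1e-12)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            nodal_centrality(complete_graph(4), "eigenvector")


class TestOracleEquivalence:
    def test_all_graphs_up_to_five_nodes(self):
        """Cp, Lp, degree and betweenness equal brute force on every
        labeled graph with <= 5 nodes (edges required for Lp)."""
        for n in (3, 4, 5):
            n_pairs = n * (n - 1) // 2
            iu = np.triu_indices(n, 1)
            for mask in range(1, 2**n_pairs):
                adj = np.zeros((n, n), dtype=bool)
                bits = [(mask >> b) & 1 for b in range(n_pairs)]
                adj[iu] = np.array(bits, dtype=bool)
                adj |= adj.T
                g = BinaryGraph(adjacency=adj, density=0.5)
                assert clustering_coefficient(g) == pytest.approx(
                    bf_clustering(adj), abs=1e-12
                )
                lp, frac = characteristic_path_length(g)
                lp_bf, frac_bf = bf_path_length(adj)
                assert lp == pytest.approx(lp_bf, abs=1e-12)
                assert frac == pytest.approx(frac_bf, abs=1e-12)
                assert np.allclose(
                    nodal_centrality(g, "degree"), bf_degree_centrality(adj)
                )
                assert np.allclose(
                    nodal_centrality(g, "betweenness"), bf_betweenness(adj),
                    atol=1e-12,
                )

    def test_random_six_and_seven_node_graphs(self, rng):
        checked = 0
        while checked < 200:
            n = int(rng.integers(6, 8))
            adj = random_graph(n, float(rng.uniform(0.2, 0.8)), rng)
            if adj.sum() == 0:
                continue
            g = BinaryGraph(adjacency=adj, density=0.5)
            assert clustering_coefficient(g) == pytest.approx(
                bf_clustering(adj), abs=1e-12
            )
            lp, frac = characteristic_path_length(g)
            lp_bf, frac_bf = bf_path_length(adj)
            assert lp == pytest.approx(lp_bf, abs=1e-12)
            assert frac == pytest.approx(frac_bf, abs=1e-12)
            assert np.allclose(
                nodal_centrality(g, "betweenness"), bf_betweenness(adj), atol=1e-12
            )
            checked += 1


class TestMetricCurves:
    def test_one_result_per_density_and_determinism(self, small_cohort):
        from funconn import compute_correlation_matrix, graphs_across_densities

        c = compute_correlation_matrix(small_cohort.subjects[0])
        densities = np.arange(10, 51, 10) / 100
        graphs = graphs_across_densities(c, densities)
        r1, c1 = metric_curves(graphs, n_nulls=5, seed=42)
        r2, c2 = metric_curves(graphs, n_nulls=5, seed=42)
        assert len(r1) == len(densities)
        assert [a.sigma for a in r1] == [a.sigma for a in r2]
        assert np.array_equal(c1, c2)
        for res in r1:
            assert res.sigma * res.lam == pytest.approx(res.gamma, rel=1e-12)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=1000))
    def test_sigma_consistency_property(self, seed):
        rng = np.random.default_rng(seed)
        adj = random_graph(20, 0.4, rng)
        if adj.sum() < 8:
            return
        g = BinaryGraph(adjacency=adj, density=0.4)
        r = small_world_index(g, n_nulls=8, seed=seed)
        assert r.sigma * r.lam == pytest.approx(r.gamma, rel=1e-12)
        assert r.cp_rand_mean > 0 and r.lp_rand_mean > 0
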