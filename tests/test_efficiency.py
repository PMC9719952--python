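import networkx as nx
import numpy as np
import pytest

from conftest import random_weighted_graph
from switchconn.efficiency import (
    DEFAULT_SPARSITIES,
    WeightedGraph,
    compare_groups,
    efficiency_curve,
    global_efficiency,
    local_efficiency,
    prepare_weighted_graph,
    threshold_by_sparsity,
    trapezoid_auc,
    weighted_shortest_paths,
)


def _nx_graph(adjacency):
    g = nx.Graph()
    n = adjacency.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if adjacency[i, j] > 0:
                g.add_edge(i, j, length=1.0 / adjacency[i, j])
    return g


def nx_global_efficiency(adjacency):
    """Independent evaluation: networkx Dijkstra + mean inverse distance."""
    g = _nx_graph(adjacency)
    n = adjacency.shape[0]
    total = 0.0
    for i in range(n):
        dist = nx.single_source_dijkstra_path_length(g, i, weight="length")
        total += sum(1.0 / d for j, d in dist.items() if j != i)
    return total / (n * (n - 1))


def nx_local_efficiency(adjacency):
    """Brute-force nodal efficiency over neighbor-induced subgraphs."""
    g = _nx_graph(adjacency)
    n = adjacency.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adjacency[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = g.subgraph(nbrs)
        acc = 0.0
        for j in nbrs:
            dist = nx.single_source_dijkstra_path_length(sub, j, weight="length")
            for h in nbrs:
                if h == j or h not in dist or dist[h] == 0:
                    continue
                acc += (adjacency[i, j] * adjacency[i, h] / dist[h]) ** (1 / 3)
        total += acc / (k * (k - 1))
    return total / n


class TestGraphPreparation:
    def test_positive_weights_preserved_diagonal_zeroed(self):
        m = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.7], [0.2, 0.7, 1.0]])
        g = prepare_weighted_graph(m)
        assert g.adjacency[0, 1] == 0.4
        assert np.all(np.diag(g.adjacency) == 0)

    def test_negative_correlations_zeroed(self):
        m = np.array([[1.0, -0.3], [-0.3, 1.0]])
        assert prepare_weighted_graph(m).adjacency[0, 1] == 0.0
        assert prepare_weighted_graph(m, negative="absolute").adjacency[0, 1] == 0.3

    def test_identity_matrix_gives_empty_graph(self):
        g = prepare_weighted_graph(np.eye(5))
        assert g.n_edges == 0

    def test_asymmetry_rejected(self):
        m = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            prepare_weighted_graph(m)


class TestSparsityThreshold:
    def test_full_sparsity_keeps_graph(self):
        g = random_weighted_graph(np.random.default_rng(0), 8, density=1.0)
        assert np.array_equal(threshold_by_sparsity(g, 1.0).adjacency, g.adjacency)

    def test_complete_ten_node_graph_at_20_percent(self):
        g = random_weighted_graph(np.random.default_rng(1), 10, density=1.0)
        assert threshold_by_sparsity(g, 0.2).n_edges == 9  # round(0.2 * 45)

    def test_surviving_edges_nested_across_sparsities(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            g = random_weighted_graph(rng, 12, density=0.9)
            sparse = threshold_by_sparsity(g, 0.2).adjacency > 0
            dense = threshold_by_sparsity(g, 0.4).adjacency > 0
            assert np.all(dense[sparse])

    def test_kept_edges_are_the_strongest(self):
        g = random_weighted_graph(np.random.default_rng(3), 10, density=1.0)
        kept = threshold_by_sparsity(g, 0.2)
        iu = np.triu_indices(10, k=1)
        surviving = kept.adjacency[iu][kept.adjacency[iu] > 0]
        dropped = g.adjacency[iu][kept.adjacency[iu] == 0]
        assert surviving.min() >= dropped.max()

    def test_insufficient_edges_warns_and_keeps_all(self):
        adj = np.zeros((6, 6))
        adj[0, 1] = adj[1, 0] = 0.5
        g = WeightedGraph(adj, [f"n{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="keeping all"):
            out = threshold_by_sparsity(g, 0.9)
        assert out.n_edges == 1

    @pytest.mark.parametrize("sparsity", [0.0, -0.1, 1.5])
    def test_invalid_sparsity_rejected(self, sparsity):
        g = random_weighted_graph(np.random.default_rng(4), 5)
        with pytest.raises(ValueError, match="sparsity"):
            threshold_by_sparsity(g, sparsity)


class TestShortestPaths:
    def test_single_edge_inverse_weight(self):
        adj = np.array([[0.0, 2.0], [2.0, 0.0]])
        d = weighted_shortest_paths(WeightedGraph(adj, ["a", "b"]))
        assert d[0, 1] == 0.5

    def test_two_hop_path(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[1, 2] = adj[2, 1] = 1.0
        d = weighted_shortest_paths(WeightedGraph(adj, list("abc")))
        assert d[0, 2] == 2.0

    def test_unreachable_pairs_infinite(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        d = weighted_shortest_paths(WeightedGraph(adj, list("abc")))
        assert np.isinf(d[0, 2])

    def test_matches_dijkstra_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = random_weighted_graph(rng, 8, density=0.6)
            d = weighted_shortest_paths(g)
            nxg = _nx_graph(g.adjacency)
            for i in range(8):
                dist = nx.single_source_dijkstra_path_length(nxg, i, weight="length")
                for j in range(8):
                    expected = dist.get(j, np.inf)
                    assert d[i, j] == pytest.approx(expected, abs=1e-10)


class TestEfficiencyMetrics:
    def test_complete_unit_graph_is_maximally_efficient(self):
        adj = np.ones((6, 6)) - np.eye(6)
        g = WeightedGraph(adj, [f"n{i}" for i in range(6)])
        assert global_efficiency(g) == pytest.approx(1.0)
        assert local_efficiency(g) == pytest.approx(1.0)

    def test_edgeless_graph_zero_global_efficiency(self):
        g = WeightedGraph(np.zeros((4, 4)), list("abcd"))
        assert global_efficiency(g) == 0.0

    def test_three_node_unit_path(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[1, 2] = adj[2, 1] = 1.0
        assert global_efficiency(WeightedGraph(adj, list("abc"))) == pytest.approx(5 / 6)

    def test_star_graph_zero_local_efficiency(self):
        adj = np.zeros((5, 5))
        adj[0, 1:] = adj[1:, 0] = 1.0
        assert local_efficiency(WeightedGraph(adj, list("abcde"))) == 0.0

    def test_unit_weight_scaling_of_global_efficiency(self):
        adj = 3.0 * (np.ones((5, 5)) - np.eye(5))
        g = WeightedGraph(adj, list("abcde"))
        assert global_efficiency(g) == pytest.approx(3.0)

    def test_matches_bruteforce_oracle_on_random_graphs(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            g = random_weighted_graph(rng, 8, density=rng.uniform(0.3, 0.9))
            assert global_efficiency(g) == pytest.approx(
                nx_global_efficiency(g.adjacency), abs=1e-10)
            assert local_efficiency(g) == pytest.approx(
                nx_local_efficiency(g.adjacency), abs=1e-10)

    def test_global_efficiency_nondecreasing_with_sparsity(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            g = random_weighted_graph(rng, 15, density=1.0)
            values = [global_efficiency(threshold_by_sparsity(g, s))
                      for s in DEFAULT_SPARSITIES]
            assert np.all(np.diff(values) >= -1e-12)

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValueError):
            global_efficiency(WeightedGraph(np.zeros((1, 1)), ["a"]))


class TestEfficiencyCurve:
    def test_default_sweep_has_ten_points(self):
        g = random_weighted_graph(np.random.default_rng(8), 12, density=1.0)
        curve = efficiency_curve(g)
        assert curve.sparsities.size == 10
        assert curve.sparsities[0] == pytest.approx(0.05)
        assert curve.sparsities[-1] == pytest.approx(0.50)

    def test_trapezoid_rectangle_and_two_point(self):
        x = np.arange(0.05, 0.51, 0.05)
        assert trapezoid_auc(x, np.full(10, 2.0)) == pytest.approx(0.45 * 2.0)
        assert trapezoid_auc([0.1, 0.2], [0.4, 0.6]) == pytest.approx(0.05)

    def test_auc_matches_curve_values(self):
        g = random_weighted_graph(np.random.default_rng(9), 10, density=1.0)
        curve = efficiency_curve(g)
        assert curve.eg_auc == pytest.approx(
            trapezoid_auc(curve.sparsities, curve.eg_values))

    def test_nonincreasing_sparsities_rejected(self):
        g = random_weighted_graph(np.random.default_rng(10), 6)
        with pytest.raises(ValueError, match="increasing"):
            efficiency_curve(g, [0.3, 0.2])


class TestGroupComparison:
    def test_identical_groups_null_result(self):
        result = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.t_statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        result = compare_groups([1, 2, 3], [4, 5, 6])
        assert result.t_statistic == pytest.approx(-3.674, abs=1e-3)
        assert result.degrees_of_freedom == 4

    def test_paper_scale_degrees_of_freedom(self):
        rng = np.random.default_rng(11)
        result = compare_groups(rng.normal(size=46), rng.normal(size=46))
        assert result.degrees_of_freedom == 90

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            compare_groups([1.0, 1.0], [1.0, 1.0])

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])
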