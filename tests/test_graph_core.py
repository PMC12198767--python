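"""Thresholding, binarization, graph metrics, density curves and AUC."""

import numpy as np
import pytest

from connres.core import ModulePartition, WeightedConnectome
from connres.graph_core import (
    DEFAULT_GRID,
    BinaryGraph,
    auc_of_curve,
    clustering_mean,
    density_stack,
    global_efficiency,
    metric_curve,
    modularity_fixed,
    participation,
    positive_threshold,
    proportional_binarize,
)


def conn_from(weights, ids=None) -> WeightedConnectome:
    w = np.asarray(weights, dtype=float)
    ids = ids or tuple(f"n{i}" for i in range(w.shape[0]))
    return WeightedConnectome(ids, w)


def graph_from(adj, ids=None) -> BinaryGraph:
    a = np.asarray(adj, dtype=bool)
    ids = ids or tuple(f"n{i}" for i in range(a.shape[0]))
    return BinaryGraph(ids, a)


def random_conn(rng, n) -> WeightedConnectome:
    w = rng.uniform(-1, 1, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 1.0)
    return conn_from(w)


class TestPositiveThreshold:
    def test_all_negative_off_diagonals_zeroed(self):
        w = -0.5 * np.ones((4, 4))
        np.fill_diagonal(w, 1.0)
        out = positive_threshold(conn_from(w))
        assert np.all(out.weights[~np.eye(4, dtype=bool)] == 0.0)

    def test_all_positive_unchanged(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.01, 1, size=(5, 5))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        conn = conn_from(w)
        assert np.array_equal(positive_threshold(conn).weights, conn.weights)

    def test_mixed_matrix_only_negatives_zeroed(self):
        w = np.array([[1.0, 0.5, -0.3], [0.5, 1.0, 0.0], [-0.3, 0.0, 1.0]])
        out = positive_threshold(conn_from(w)).weights
        assert out[0, 1] == 0.5 and out[0, 2] == 0.0 and out[1, 2] == 0.0


class TestProportionalBinarize:
    def test_delta_zero_edgeless_and_one_all_positive(self):
        rng = np.random.default_rng(1)
        conn = random_conn(rng, 8)
        assert proportional_binarize(conn, 0.0).n_edges == 0
        n_pos = int((np.triu(conn.weights, 1) > 0).sum())
        assert proportional_binarize(conn, 1.0).n_edges == n_pos

    def test_half_density_keeps_three_strongest_of_six(self):
        w = np.ones((4, 4))
        vals = {(0, 1): 0.9, (0, 2): 0.7, (0, 3): 0.5,
                (1, 2): 0.3, (1, 3): 0.2, (2, 3): 0.1}
        for (i, j), v in vals.items():
            w[i, j] = w[j, i] = v
        g = proportional_binarize(conn_from(w), 0.5)
        assert g.n_edges == 3
        assert g.adjacency[0, 1] and g.adjacency[0, 2] and g.adjacency[0, 3]

    def test_tie_break_deterministic(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 1.0)
        g1 = proportional_binarize(conn_from(w), 0.5)
        g2 = proportional_binarize(conn_from(w), 0.5)
        assert np.array_equal(g1.adjacency, g2.adjacency)
        # lexicographically earliest pairs win the tie
        assert g1.adjacency[0, 1] and g1.adjacency[0, 2] and g1.adjacency[0, 3]

    def test_invalid_density_rejected(self):
        conn = random_conn(np.random.default_rng(2), 4)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            proportional_binarize(conn, 1.5)


class TestDensityStack:
    def test_default_grid_gives_ten_graphs(self):
        conn = random_conn(np.random.default_rng(3), 12)
        stack = density_stack(conn)
        assert len(stack) == 10

    def test_nested_edge_sets(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            stack = density_stack(random_conn(rng, rng.integers(4, 15)))
            for lo, hi in zip(stack, stack[1:]):
                assert not np.any(lo.adjacency & ~hi.adjacency)

    def test_full_density_on_positive_weights_is_complete(self):
        n = 6
        w = np.full((n, n), 0.4)
        np.fill_diagonal(w, 1.0)
        (g,) = density_stack(conn_from(w), grid=[1.0])
        assert g.n_edges == n * (n - 1) // 2


class TestMetrics:
    def test_complete_graph_efficiency_one(self):
        assert global_efficiency(graph_from(~np.eye(4, dtype=bool))) == 1.0

    def test_edgeless_graph_efficiency_zero(self):
        assert global_efficiency(graph_from(np.zeros((4, 4)))) == 0.0

    def test_path_of_three_nodes(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert global_efficiency(graph_from(adj)) == pytest.approx(5 / 6)

    def test_two_triangles_modularity_half(self, toy_partition):
        adj = np.zeros((6, 6), dtype=bool)
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            adj[i, j] = adj[j, i] = True
        g = graph_from(adj, ids=tuple("abcdef"))
        assert modularity_fixed(g, toy_partition) == pytest.approx(0.5)

    def test_single_module_partition_q_zero(self):
        rng = np.random.default_rng(5)
        adj = np.triu(rng.random((7, 7)) < 0.5, 1)
        adj = adj | adj.T
        part = ModulePartition(
            tuple(f"n{i}" for i in range(7)), np.zeros(7, dtype=int)
        )
        assert modularity_fixed(graph_from(adj), part) == pytest.approx(0.0)

    def test_edgeless_graph_q_zero(self, toy_partition):
        g = graph_from(np.zeros((6, 6)), ids=tuple("abcdef"))
        assert modularity_fixed(g, toy_partition) == 0.0

    def test_triangle_clustering_one_star_zero(self):
        tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        assert clustering_mean(graph_from(tri)) == 1.0
        star = np.zeros((4, 4), dtype=bool)
        star[0, 1:] = star[1:, 0] = True
        assert clustering_mean(graph_from(star)) == 0.0

    def test_participation_spot_values(self):
        # degree-4 node with 2 edges into each of 2 modules -> PC = 0.5
        adj = np.zeros((5, 5), dtype=bool)
        adj[0, 1:] = adj[1:, 0] = True
        part = ModulePartition(
            tuple(f"n{i}" for i in range(5)), np.array([0, 1, 1, 2, 2])
        )
        pc = participation(graph_from(adj), part)
        assert pc["n0"] == pytest.approx(0.5)
        # all edges intra-module -> 0; isolated node -> 0
        intra = np.zeros((5, 5), dtype=bool)
        intra[1, 2] = intra[2, 1] = True
        pc = participation(graph_from(intra), part)
        assert pc["n1"] == 0.0 and pc["n0"] == 0.0

    def test_pc_even_spread_over_17_modules(self):
        n = 18
        adj = np.zeros((n, n), dtype=bool)
        adj[0, 1:] = adj[1:, 0] = True  # degree 17, one edge per module
        modules = np.concatenate([[0], np.arange(17)])
        part = ModulePartition(tuple(f"n{i}" for i in range(n)), modules)
        pc = participation(graph_from(adj), part)
        assert pc["n0"] == pytest.approx(1 - 1 / 17)

    def test_size_guards(self, toy_partition):
        one = graph_from(np.zeros((1, 1)))
        with pytest.raises(ValueError, match="2 nodes"):
            global_efficiency(one)
        two = graph_from(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="3 nodes"):
            clustering_mean(two)
        g = graph_from(np.zeros((3, 3)), ids=("a", "b", "zzz"))
        with pytest.raises(KeyError, match="zzz"):
            modularity_fixed(g, toy_partition)

    def test_metrics_invariant_under_relabeling(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = rng.integers(5, 14)
            adj = np.triu(rng.random((n, n)) < 0.4, 1)
            adj = adj | adj.T
            ids = tuple(f"n{i}" for i in range(n))
            part = ModulePartition(ids, rng.integers(0, 3, size=n))
            g = graph_from(adj, ids)
            perm = rng.permutation(n)
            gp = BinaryGraph(
                tuple(ids[i] for i in perm), adj[np.ix_(perm, perm)]
            )
            assert global_efficiency(g) == pytest.approx(
                global_efficiency(gp), abs=1e-12
            )
            assert clustering_mean(g) == pytest.approx(
                clustering_mean(gp), abs=1e-12
            )
            assert modularity_fixed(g, part) == pytest.approx(
                modularity_fixed(gp, part), abs=1e-12
            )
            pc, pcp = participation(g, part), participation(gp, part)
            assert all(pc[i] == pytest.approx(pcp[i], abs=1e-12) for i in ids)


class TestCurvesAndAuc:
    def test_flat_curve_integrates_to_constant(self):
        grid = DEFAULT_GRID
        assert auc_of_curve(grid, [0.7] * 10, value_at_zero=0.7) == pytest.approx(0.7)

    def test_linear_curve_integrates_to_half(self):
        assert auc_of_curve(DEFAULT_GRID, list(DEFAULT_GRID)) == pytest.approx(0.5)

    def test_matches_independent_trapezoid_sum(self):
        rng = np.random.default_rng(7)
        vals = rng.random(10)
        x = np.concatenate([[0.0], DEFAULT_GRID])
        y = np.concatenate([[0.0], vals])
        expected = sum(
            (x[i + 1] - x[i]) * (y[i + 1] + y[i]) / 2 for i in range(10)
        )
        assert auc_of_curve(DEFAULT_GRID, vals) == pytest.approx(
            expected, abs=1e-14
        )

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            auc_of_curve([0.2, 0.1], [1.0, 1.0])

    def test_complete_positive_matrix_full_density_efficiency_one(self):
        # proportional thresholding keeps only delta*P edges, so E_glob
        # reaches 1 exactly at delta = 1 where the complete graph returns
        n = 8
        w = np.full((n, n), 0.5)
        np.fill_diagonal(w, 1.0)
        curve = metric_curve(conn_from(w), "global_efficiency")
        assert curve.values[-1] == 1.0
        assert all(b >= a for a, b in zip(curve.values, curve.values[1:]))
        assert 0.0 < curve.auc < 1.0

    def test_zero_matrix_all_zero(self):
        w = np.zeros((5, 5))
        np.fill_diagonal(w, 1.0)
        curve = metric_curve(conn_from(w), "global_efficiency")
        assert curve.auc == 0.0 and set(curve.values) == {0.0}

    def test_efficiency_curve_monotone_nondecreasing(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            conn = random_conn(rng, rng.integers(5, 16))
            curve = metric_curve(conn, "global_efficiency")
            diffs = np.diff(curve.values)
            assert np.all(diffs >= -1e-12)

    def test_partition_required_for_modularity(self):
        conn = random_conn(np.random.default_rng(9), 5)
        with pytest.raises(ValueError, match="partition"):
            metric_curve(conn, "modularity")
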