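import numpy as np
import pytest

from nqmod import (
    MetricVector,
    Partition,
    WeightedNetwork,
    build_multiplex,
    clustering_multiplex,
    clustering_single,
    degree_multiplex,
    degree_single,
    metric_vs_nq,
    nodal_modularity_single,
    pagerank_multiplex_combined,
    pagerank_single,
)
from nqmod.metrics import MetricError

from conftest import random_multiplex


def ring(n=8, names=None):
    A = np.zeros((n, n))
    for i in range(n):
        A[i, (i + 1) % n] = A[(i + 1) % n, i] = 1.0
    return WeightedNetwork(names or [f"n{i}" for i in range(n)], A)


def triangle():
    return WeightedNetwork(list("abc"), np.ones((3, 3)) - np.eye(3))


class TestDegree:
    def test_triangle_layers_with_unit_coupling(self):
        mux = build_multiplex([triangle(), triangle()], 1.0)
        np.testing.assert_allclose(degree_multiplex(mux).values, 3.0)

    def test_zero_coupling_equals_intra_strength(self):
        mux = build_multiplex([triangle(), triangle()], 0.0)
        np.testing.assert_allclose(degree_multiplex(mux).values, 2.0)

    def test_random_instance_matches_brute_force(self):
        rng = np.random.default_rng(1)
        mux = random_multiplex(rng, n_nodes=7, n_layers=3)
        mv = degree_multiplex(mux)
        for s in range(3):
            for i in range(7):
                expected = mux.layers[s].weights[i].sum() + sum(
                    mux.coupling[s, r] for r in range(3) if r != s)
                assert mv.values[i + s * 7] == pytest.approx(expected, abs=1e-12)


class TestClusteringMultiplex:
    def test_single_two_triangle_fixture(self):
        A1 = np.zeros((3, 3))
        A1[0, 1] = A1[1, 0] = 1.0
        A1[0, 2] = A1[2, 0] = 1.0
        A2 = np.zeros((3, 3))
        A2[1, 2] = A2[2, 1] = 1.0
        mux = build_multiplex(
            [WeightedNetwork(list("abc"), A1), WeightedNetwork(list("abc"), A2)], 1.0)
        values = clustering_multiplex(mux).values
        # node a: one one-triad in layer 1, closed by layer 2 -> 1.0
        assert values[0] == pytest.approx(1.0)

    def test_empty_layers_zero_by_convention(self):
        empty = WeightedNetwork(list("abc"), np.zeros((3, 3)))
        mux = build_multiplex([empty, empty], 1.0)
        np.testing.assert_array_equal(clustering_multiplex(mux).values, 0.0)

    def test_identical_complete_layers_all_ones(self):
        n = 5
        K = WeightedNetwork([f"n{i}" for i in range(n)],
                            np.ones((n, n)) - np.eye(n))
        mux = build_multiplex([K, K], 1.0)
        np.testing.assert_allclose(clustering_multiplex(mux).values, 1.0)

    def test_invariant_to_positive_weight_rescaling(self):
        rng = np.random.default_rng(6)
        mux = random_multiplex(rng, n_nodes=8, n_layers=2)
        base = clustering_multiplex(mux).values
        scaled_layers = [WeightedNetwork(l.node_labels, 4.2 * l.weights)
                         for l in mux.layers]
        scaled = clustering_multiplex(build_multiplex(scaled_layers, 1.0)).values
        np.testing.assert_allclose(scaled, base, atol=1e-12)

    def test_three_layers_unsupported(self):
        t = triangle()
        with pytest.raises(MetricError, match="2 layers"):
            clustering_multiplex(build_multiplex([t, t, t], 1.0))


class TestPageRank:
    def test_ring_layers_uniform(self):
        mux = build_multiplex([ring(), ring()], 1.0)
        values = pagerank_multiplex_combined(mux).values
        np.testing.assert_allclose(values, 1.0 / 8.0, atol=1e-6)

    def test_per_layer_normalization(self):
        rng = np.random.default_rng(2)
        mux = random_multiplex(rng, n_nodes=9, n_layers=2)
        values = pagerank_multiplex_combined(mux).values
        assert values[:9].sum() == pytest.approx(1.0, abs=1e-8)
        assert values[9:].sum() == pytest.approx(1.0, abs=1e-8)

    def test_uniform_bias_reduces_to_standard_pagerank(self):
        rng = np.random.default_rng(4)
        mux = random_multiplex(rng, n_nodes=10, n_layers=2)
        from nqmod.metrics import _pagerank_power

        target = mux.layers[1].weights
        uniform = np.ones(10)
        biased = _pagerank_power(target, 0.85, 1e-12, 10000,
                                 weights_bias=uniform,
                                 teleport=uniform)
        plain = _pagerank_power(target, 0.85, 1e-12, 10000)
        np.testing.assert_allclose(biased, plain, atol=1e-9)

    def test_single_layer_matches_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(8)
        for _ in range(5):
            n = int(rng.integers(5, 20))
            A = (rng.random((n, n)) < 0.4) * rng.uniform(0.2, 2.0, (n, n))
            A = np.triu(A, 1)
            A = A + A.T
            if A.sum() == 0:
                A[0, 1] = A[1, 0] = 1.0
            net = WeightedNetwork([f"n{i}" for i in range(n)], A)
            mine = pagerank_single(net).values
            g = net.to_networkx()
            # isolates teleport in both conventions
            ref = nx.pagerank(g, alpha=0.85, weight="weight", tol=1e-12)
            ref_v = np.array([ref.get(lbl, 0) for lbl in net.node_labels])
            iso = [i for i, lbl in enumerate(net.node_labels) if lbl not in g
                   or g.degree(lbl) == 0]
            keep = [i for i in range(n) if i not in iso]
            np.testing.assert_allclose(mine[keep], ref_v[keep], atol=1e-6)


class TestSingleLayerCrossChecks:
    def test_clustering_matches_hand_formula(self):
        rng = np.random.default_rng(10)
        n = 12
        A = (rng.random((n, n)) < 0.4).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        net = WeightedNetwork([f"n{i}" for i in range(n)], A)
        mine = clustering_single(net).values
        deg = A.sum(axis=1)
        tri = np.diag(A @ A @ A) / 2.0
        expected = np.divide(2 * tri, deg * (deg - 1),
                             out=np.zeros(n), where=deg > 1)
        np.testing.assert_allclose(mine, expected, atol=1e-12)

    def test_degree_is_row_sum(self):
        rng = np.random.default_rng(11)
        mux = random_multiplex(rng, n_nodes=6, n_layers=1)
        net = mux.layers[0]
        np.testing.assert_allclose(degree_single(net).values,
                                   net.weights.sum(axis=1))


class TestMetricVsNq:
    def _nq(self):
        # asymmetric graph so nQ varies across nodes
        rng = np.random.default_rng(0)
        mux = random_multiplex(rng, n_nodes=8, n_layers=1)
        net = mux.layers[0]
        part = Partition.single_layer(np.arange(8) % 2)
        return nodal_modularity_single(net, part)

    def test_identical_vectors_r_one(self):
        nq = self._nq()
        mv = MetricVector("copy", nq.values.copy(), nq.node_labels)
        assert metric_vs_nq(mv, nq)["r"] == pytest.approx(1.0)

    def test_negated_vector_r_minus_one(self):
        nq = self._nq()
        mv = MetricVector("neg", -nq.values, nq.node_labels)
        assert metric_vs_nq(mv, nq)["r"] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        nq = self._nq()
        mv = MetricVector("const", np.ones_like(nq.values), nq.node_labels)
        with pytest.raises(MetricError, match="zero variance"):
            metric_vs_nq(mv, nq)

    def test_per_node_metric_broadcast_over_layers(self):
        rng = np.random.default_rng(3)
        mux = random_multiplex(rng, n_nodes=6, n_layers=2)
        from nqmod import nodal_modularity_multiplex
        from conftest import random_partition

        nq = nodal_modularity_multiplex(mux, random_partition(rng, 6, 2))
        mv = clustering_multiplex(mux)  # per node
        rep = metric_vs_nq(mv, nq)
        assert rep["pairs"].shape == (12, 2)
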