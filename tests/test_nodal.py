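import numpy as np
import pytest

from nqmod import (
    CommunityError,
    Partition,
    QualityParams,
    StatsError,
    WeightedNetwork,
    build_multiplex,
    multislice_quality,
    nodal_modularity_multiplex,
    nodal_modularity_single,
    nq_group_table,
)

from conftest import brute_force_nq, random_multiplex, random_partition


class TestClosedFormFixtures:
    def test_single_layer_cliques_each_node_one_twelfth(self, clique_net, clique_partition):
        res = nodal_modularity_single(clique_net, clique_partition)
        np.testing.assert_allclose(res.values, 1.0 / 12.0, atol=1e-12)
        assert res.total_Q == pytest.approx(0.5, abs=1e-12)

    def test_singleton_partition_only_self_null_term(self, clique_net):
        # nQ_i = -k_i^2 / (4 m^2): for the clique fixture -1/36 per node
        res = nodal_modularity_single(clique_net, Partition.single_layer(range(6)))
        np.testing.assert_allclose(res.values, -1.0 / 36.0, atol=1e-12)

    def test_dual_layer_cliques_each_node_layer(self, dual_clique_mux, dual_clique_partition):
        res = nodal_modularity_multiplex(dual_clique_mux, dual_clique_partition,
                                         QualityParams(mu_convention="coupled"))
        np.testing.assert_allclose(res.values, 1.0 / 18.0, atol=1e-12)
        assert res.total_Q == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_zero_coupling_rescaled_single_layer_values(self, clique_net, clique_partition):
        mux = build_multiplex([clique_net, clique_net], 0.0)
        part = Partition.from_layers([[0, 0, 0, 1, 1, 1], [2, 2, 2, 3, 3, 3]])
        res = nodal_modularity_multiplex(mux, part)
        single = nodal_modularity_single(clique_net, clique_partition)
        # multiplex normalization doubles 2mu, halving each contribution
        np.testing.assert_allclose(res.values, np.tile(single.values / 2, 2),
                                   atol=1e-12)


class TestConservationAndReduction:
    @pytest.mark.parametrize("mu", ["coupled", "intra_only"])
    def test_sum_nq_equals_global_q(self, mu):
        rng = np.random.default_rng(99)
        for _ in range(25):
            mux = random_multiplex(rng)
            part = random_partition(rng, mux.n_nodes, mux.n_layers)
            params = QualityParams(mu_convention=mu)
            nq = nodal_modularity_multiplex(mux, part, params)
            q = multislice_quality(mux, part, params).Q
            assert nq.values.sum() == pytest.approx(q, abs=1e-10)

    def test_multiplex_reduces_to_single_layer_form(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            mux = random_multiplex(rng, n_layers=1)
            net = mux.layers[0]
            part = random_partition(rng, mux.n_nodes, 1)
            multi = nodal_modularity_multiplex(mux, part)
            single = nodal_modularity_single(net, part)
            np.testing.assert_array_equal(multi.values, single.values)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            mux = random_multiplex(rng)
            part = random_partition(rng, mux.n_nodes, mux.n_layers)
            oracle_vals, _ = brute_force_nq(mux, part)
            nq = nodal_modularity_multiplex(mux, part)
            np.testing.assert_allclose(nq.values, oracle_vals, atol=1e-12)

    def test_single_layer_sum_matches_direct_modularity_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            mux = random_multiplex(rng, n_layers=1)
            net = mux.layers[0]
            part = random_partition(rng, net.n_nodes, 1)
            nq = nodal_modularity_single(net, part)
            A, k = net.weights, net.strengths
            two_m = 2 * net.total_weight
            same = part.labels[:, None] == part.labels[None, :]
            q_direct = ((A - np.outer(k, k) / two_m) * same).sum() / two_m
            assert nq.values.sum() == pytest.approx(q_direct, abs=1e-12)


class TestStructuralProperties:
    def test_node_relabelling_permutes_nq(self):
        rng = np.random.default_rng(31)
        mux = random_multiplex(rng, n_nodes=8, n_layers=2)
        part = random_partition(rng, 8, 2)
        nq = nodal_modularity_multiplex(mux, part)
        perm = rng.permutation(8)
        layers_p = [
            WeightedNetwork([layer.node_labels[i] for i in perm],
                            layer.weights[np.ix_(perm, perm)])
            for layer in mux.layers
        ]
        mux_p = build_multiplex(layers_p, mux.coupling[0, 1])
        labels_p = np.concatenate([part.layer_labels(s)[perm] for s in range(2)])
        nq_p = nodal_modularity_multiplex(
            mux_p, Partition(labels_p, 8, 2))
        expected = np.concatenate([nq.layer_values(s)[perm] for s in range(2)])
        np.testing.assert_allclose(nq_p.values, expected, atol=1e-12)

    def test_invariant_under_global_weight_rescaling(self):
        rng = np.random.default_rng(77)
        mux = random_multiplex(rng, n_nodes=10, n_layers=2, coupling=1.5)
        part = random_partition(rng, 10, 2)
        nq = nodal_modularity_multiplex(mux, part)
        c = 3.7
        layers_c = [WeightedNetwork(l.node_labels, c * l.weights)
                    for l in mux.layers]
        mux_c = build_multiplex(layers_c, c * 1.5)
        nq_c = nodal_modularity_multiplex(mux_c, part)
        np.testing.assert_allclose(nq_c.values, nq.values, atol=1e-12)

    def test_within_module_gain_raises_own_nq_lowers_neighbours(self):
        """Strengthening one node-layer's within-module edge increases its
        nQ, while an untouched same-module node-layer with a positive
        contribution loses nQ through the shared renormalization (2mu and
        strength terms), despite no change in its own connectivity."""
        def toy(w_ab_layer1):
            A1 = np.array([[0, w_ab_layer1, 0.0],
                           [w_ab_layer1, 0, 5.0],
                           [0.0, 5.0, 0]], dtype=float)
            A2 = np.array([[0, 1.0, 0.0], [1.0, 0, 5.0], [0.0, 5.0, 0]])
            names = ["a", "b", "c"]
            mux = build_multiplex(
                [WeightedNetwork(names, A1), WeightedNetwork(names, A2)], 0.1)
            part = Partition.from_layers([[0, 0, 1], [0, 0, 1]])
            return nodal_modularity_multiplex(mux, part)

        before = toy(1.0)
        after = toy(1.5)
        # node a, layer 1 gains within-module weight -> nQ strictly up
        assert after.values[0] > before.values[0]
        # node a, layer 2 is untouched but shares the module -> strictly down
        assert before.values[3] > 0
        assert after.values[3] < before.values[3]

    def test_per_node_reducer_sums_layers(self, dual_clique_mux, dual_clique_partition):
        nq = nodal_modularity_multiplex(dual_clique_mux, dual_clique_partition)
        np.testing.assert_allclose(nq.per_node(), 2.0 / 18.0, atol=1e-12)

    def test_partition_size_mismatch_rejected(self, dual_clique_mux):
        with pytest.raises(CommunityError, match="node-layers"):
            nodal_modularity_multiplex(dual_clique_mux,
                                       Partition.single_layer([0] * 6))


class TestGroupTable:
    def _results(self, rng, n_subjects, labels=("a", "b", "c")):
        mux = random_multiplex(rng, n_nodes=5, n_layers=2)
        out = []
        for _ in range(n_subjects):
            part = random_partition(rng, 5, 2)
            out.append(nodal_modularity_multiplex(mux, part))
        return out

    def test_three_subjects_two_groups(self):
        rng = np.random.default_rng(0)
        res = self._results(rng, 3)
        study = nq_group_table(res, ["control", "control", "patient"])
        assert study.values.shape == (3, 10)
        assert study.group_names == ["control", "patient"]

    def test_mismatched_roi_sets_rejected(self):
        rng = np.random.default_rng(0)
        a = self._results(rng, 1)[0]
        b = self._results(rng, 1)[0]
        b.node_labels = list(b.node_labels)
        b.node_labels[0] = "other"
        with pytest.raises(StatsError, match="mismatch"):
            nq_group_table([a, b], ["x", "y"])

    def test_study_round_trips_through_tsv(self, tmp_path):
        from nqmod.io import read_study, write_study

        rng = np.random.default_rng(4)
        res = self._results(rng, 4)
        study = nq_group_table(res, ["g1", "g1", "g2", "g2"])
        path = tmp_path / "study.tsv"
        write_study(study, path)
        back = read_study(path)
        np.testing.assert_array_equal(back.values, study.values)
        assert back.groups == study.groups
        assert back.node_labels == study.node_labels
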