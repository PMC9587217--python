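"""Multilayer modularity: quality function, Louvain, partition dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from micromod.networks import FunctionalNetwork
from micromod.multilayer import (
    MultilayerNetwork,
    MultilayerPartition,
    build_multilayer,
    compare_to_surrogates,
    exhaustive_max_quality,
    louvain_optimize,
    normalized_persistence,
    quality,
    stationarity,
)


def _part(labels):
    labels = np.asarray(labels)
    return MultilayerPartition(labels=labels, quality=0.0, gamma=1.0, omega=0.0)


def _random_mlnet(n, S, seed, p=0.5):
    rng = np.random.default_rng(seed)
    layers = []
    for _ in range(S):
        a = rng.random((n, n)) * (rng.random((n, n)) < p)
        np.fill_diagonal(a, 0)
        layers.append(a)
    nz = np.concatenate([a[a > 0] for a in layers])
    return MultilayerNetwork(layers=layers, omega=float(np.median(nz)))


class TestBuild:
    def test_omega_is_median_nonzero(self):
        layers = [np.array([[0, 1.0], [2.0, 0]]), np.array([[0, 3.0], [4.0, 0]])]
        nets = [FunctionalNetwork(a) for a in layers]
        assert build_multilayer(nets).omega == 2.5

    def test_omega_scales_with_weights(self):
        layers = [np.array([[0, 1.0], [2.0, 0]]), np.array([[0, 3.0], [4.0, 0]])]
        m1 = build_multilayer([FunctionalNetwork(a) for a in layers])
        m2 = build_multilayer([FunctionalNetwork(2 * a) for a in layers])
        assert m2.omega == 2 * m1.omega

    def test_all_zero_weights_warn(self):
        with pytest.warns(UserWarning):
            m = build_multilayer([FunctionalNetwork(np.zeros((3, 3)))])
        assert m.omega == 0.0


class TestQuality:
    def test_single_community_single_layer_is_zero(self):
        net = _random_mlnet(6, 1, 0)
        labels = np.zeros((6, 1), dtype=int)
        assert abs(quality(net, labels)) < 1e-12

    def test_two_directed_cliques(self):
        a = np.zeros((8, 8))
        for blk in (range(4), range(4, 8)):
            for i in blk:
                for j in blk:
                    if i != j:
                        a[i, j] = 1.0
        net = MultilayerNetwork(layers=[a], omega=0.0)
        labels = np.repeat([0, 1], 4).reshape(8, 1)
        assert np.isclose(quality(net, labels), 0.5)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        net = _random_mlnet(5, 2, seed)
        labels = rng.integers(0, 4, size=(5, 2))
        assert quality(net, labels) <= 1.0 + 1e-12

    def test_label_permutation_invariance(self):
        net = _random_mlnet(6, 3, 1)
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 3, size=(6, 3))
        perm = np.array([2, 0, 1])
        assert np.isclose(quality(net, labels), quality(net, perm[labels]))


class TestLouvain:
    def test_planted_modules_recovered_across_layers(self):
        rng = np.random.default_rng(0)
        n, S = 12, 3
        truth = np.repeat([0, 1], n // 2)
        layers = []
        for _ in range(S):
            a = np.zeros((n, n))
            same = truth[:, None] == truth[None, :]
            a[same] = (rng.random((n, n)) * (rng.random((n, n)) < 0.8))[same]
            a[~same] = (rng.random((n, n)) * 0.2 * (rng.random((n, n)) < 0.1))[~same]
            np.fill_diagonal(a, 0)
            layers.append(a)
        net = MultilayerNetwork(layers=layers, omega=0.3)
        part = louvain_optimize(net, n_restarts=100, seed=1)
        from sklearn.metrics import adjusted_rand_score

        for s in range(S):
            assert adjusted_rand_score(truth, part.labels[:, s]) == 1.0

    def test_quality_reproducible_from_labels(self):
        net = _random_mlnet(8, 2, 5)
        part = louvain_optimize(net, n_restarts=50, seed=2)
        assert np.isclose(part.quality, quality(net, part.labels, part.gamma))

    def test_best_of_restarts_is_maximum(self):
        net = _random_mlnet(8, 2, 6)
        part = louvain_optimize(net, n_restarts=50, seed=3)
        assert part.quality >= part.restart_qualities.max() - 1e-12

    def test_matches_exhaustive_on_small_instances(self):
        for seed in range(3):
            net = _random_mlnet(5, 2, 20 + seed)
            part = louvain_optimize(net, n_restarts=200, seed=seed)
            assert np.isclose(part.quality, exhaustive_max_quality(net), atol=1e-12)

    def test_large_gamma_gives_singletons(self):
        net = _random_mlnet(6, 1, 7)
        part = louvain_optimize(net, gamma=100.0, n_restarts=20, seed=0)
        assert len(np.unique(part.labels[:, 0])) == 6

    def test_seed_determinism(self):
        net = _random_mlnet(8, 2, 8)
        p1 = louvain_optimize(net, n_restarts=30, seed=11)
        p2 = louvain_optimize(net, n_restarts=30, seed=11)
        assert np.array_equal(p1.labels, p2.labels)


class TestDynamics:
    def test_identical_partitions(self):
        labels = np.tile(np.array([0, 0, 1, 1])[:, None], (1, 4))
        assert stationarity(_part(labels)) == 1.0
        assert normalized_persistence(_part(labels)) == 1.0

    def test_no_surviving_pairs(self):
        labels = np.array([[0, 0], [0, 1], [1, 2], [1, 3]])
        assert stationarity(_part(labels)) == 0.0

    def test_worked_jaccard_example(self):
        # layer 1: AABB, layer 2: AABA -> intersection {12}, union 4 pairs
        labels = np.array([[0, 0], [0, 0], [1, 1], [1, 0]])
        assert stationarity(_part(labels)) == 0.25

    def test_persistence_counting(self):
        labels = np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1], [1, 2, 2]])
        assert normalized_persistence(_part(labels)) == 7 / 8

    def test_every_node_changes(self):
        labels = np.array([[0, 1], [1, 2], [2, 3]])
        assert normalized_persistence(_part(labels)) == 0.0

    def test_single_layer_errors(self):
        labels = np.zeros((4, 1), dtype=int)
        with pytest.raises(ValueError):
            stationarity(_part(labels))
        with pytest.raises(ValueError):
            normalized_persistence(_part(labels))

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, size=(6, 4))
        perm = np.array([1, 2, 0])
        for fn in (stationarity, normalized_persistence):
            assert np.isclose(fn(_part(labels)), fn(_part(perm[labels])))


class TestSurrogateComparison:
    def test_planted_real_above_surrogates(self):
        from micromod.networks import degree_matched_surrogates

        rng = np.random.default_rng(0)
        n = 12
        truth = np.repeat([0, 1], n // 2)
        nets, ensembles = [], []
        for s in range(2):
            a = np.zeros((n, n))
            same = truth[:, None] == truth[None, :]
            a[same] = (rng.random((n, n)) < 0.7)[same]
            a[~same] = (rng.random((n, n)) < 0.05)[~same]
            np.fill_diagonal(a, 0)
            net = FunctionalNetwork(a)
            nets.append(net)
            ensembles.append(degree_matched_surrogates(net, n=20, passes=20, seed=s))

        def metric(layers):
            net = build_multilayer([FunctionalNetwork(a) for a in layers])
            return louvain_optimize(net, n_restarts=30, seed=0).quality

        out = compare_to_surrogates(nets, ensembles, metric)
        assert out["real"] > np.percentile(out["surrogates"], 95)

    def test_empty_ensemble_errors(self):
        with pytest.raises(ValueError):
            compare_to_surrogates([], [], lambda layers: 0.0)
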