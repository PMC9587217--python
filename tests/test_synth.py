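"""Synthetic-data generator: layouts, planted maps, VAR LFP, spikes."""

import numpy as np
import pytest

from micromod.layout import drop_corners, make_layout
from micromod.geometry import module_compactness, module_diameter
from micromod.synth import (
    VARGroundTruth,
    companion_spectral_radius,
    generate_spikes,
    generate_var_lfp,
    module_tuning,
    plant_modules,
    simulate_var,
)


class TestLayout:
    def test_span_and_count(self):
        lay = make_layout(8, 8, 0.4)
        assert lay.n_electrodes == 64
        assert np.allclose(lay.coords.max(axis=0), [2.8, 2.8])

    def test_2x2_coordinates(self):
        lay = make_layout(2, 2, 1.0)
        assert {tuple(c) for c in lay.coords} == {(0, 0), (1, 0), (0, 1), (1, 1)}

    def test_corner_dropping_keeps_96(self):
        lay = make_layout(10, 10, 0.4)
        reduced, keep = drop_corners(lay)
        assert reduced.n_electrodes == 96
        assert {0, 9, 90, 99}.isdisjoint(set(keep))

    @pytest.mark.parametrize("rows,cols,pitch", [(1, 4, 0.4), (4, 4, 0.0), (0, 0, 1.0)])
    def test_invalid_dimensions_rejected(self, rows, cols, pitch):
        with pytest.raises(ValueError):
            make_layout(rows, cols, pitch)

    def test_neighbor_pairs_are_one_pitch(self):
        lay = make_layout(3, 3, 0.5)
        pairs = lay.neighbor_pairs()
        assert len(pairs) == 12  # 2*3*2 horizontal + vertical
        d = np.linalg.norm(lay.coords[pairs[:, 0]] - lay.coords[pairs[:, 1]], axis=1)
        assert np.allclose(d, 0.5)


class TestPlantModules:
    def test_quadrant_tiling_diameter(self):
        lay = make_layout(8, 8, 0.4)
        pm = plant_modules(lay, 4, target_diameter=1.3, seed=0)
        diams = module_diameter(pm.labels, lay)
        # 4x4 quadrant: 2 R_g = 2 sqrt(2 * 0.4^2 * 15 / 12)
        expect = 2 * np.sqrt(2 * 0.4**2 * 15 / 12)
        assert np.allclose(list(diams.values()), expect)
        assert all(v == 1.0 for v in module_compactness(pm.labels, lay).values())

    def test_single_module(self, layout44):
        pm = plant_modules(layout44, 1)
        assert pm.n_modules == 1 and np.all(pm.labels == 0)

    def test_seed_determinism_and_contiguity(self):
        lay = make_layout(6, 5, 0.4)  # 30 electrodes, 4 does not tile evenly
        pm1 = plant_modules(lay, 4, seed=5)
        pm2 = plant_modules(lay, 4, seed=5)
        assert np.array_equal(pm1.labels, pm2.labels)
        from micromod.synth import _is_contiguous

        assert all(_is_contiguous(lay, pm1.labels, m) for m in range(4))

    def test_infeasible_target_warns(self, layout44):
        with pytest.warns(UserWarning):
            plant_modules(layout44, 2, target_diameter=10.0, seed=0)


class TestVARTruth:
    def test_constructed_truth_is_stable(self, var_truth):
        assert var_truth.is_stable()
        assert var_truth.spectral_radius() < 0.95

    def test_unstable_truth_rejected(self, planted2):
        coeffs = np.zeros((1, 16, 16))
        coeffs[0] = np.eye(16) * 1.05
        truth = VARGroundTruth(order=1, coeffs=coeffs, noise_cov=np.eye(16))
        with pytest.raises(ValueError, match="spectral radius"):
            generate_var_lfp(planted2, truth, n_blocks=1, block_len=1.0)

    def test_block_variance_stationarity(self, var_blocks):
        v = np.array([b.var() for b in var_blocks.blocks])
        assert v.max() / v.min() < 3.0

    def test_seed_determinism(self, planted2, var_truth):
        _, b1, _ = generate_var_lfp(planted2, var_truth, n_blocks=2, block_len=1.0, seed=9)
        _, b2, _ = generate_var_lfp(planted2, var_truth, n_blocks=2, block_len=1.0, seed=9)
        assert np.array_equal(b1.blocks[0], b2.blocks[0])

    def test_independent_channels_give_null_gc(self):
        from micromod.granger import conditional_gc_matrix, gc_significance
        from micromod.session import BlockSet

        rng = np.random.default_rng(0)
        coeffs = np.zeros((2, 5, 5))
        coeffs[0] = np.eye(5) * 0.4
        truth = VARGroundTruth(order=2, coeffs=coeffs, noise_cov=np.eye(5) * 0.01)
        x = simulate_var(truth, 40000, rng)
        blocks = BlockSet(blocks=[x[:, i * 4000 : (i + 1) * 4000] for i in range(10)], fs=1000.0)
        sig = gc_significance(conditional_gc_matrix(blocks, 2))
        assert sig.mask.sum() == 0

    def test_companion_radius_matches_scalar_ar(self):
        coeffs = np.array([[[0.7]]])
        assert np.isclose(companion_spectral_radius(coeffs), 0.7)


class TestSpikes:
    def test_poisson_baseline_mean(self, planted2):
        tuning = module_tuning(planted2, gain=1.0, baseline_rate=1.5, seed=0)
        spikes, trials = generate_spikes(planted2, tuning, n_trials=40, seed=1)
        # flat-gain units: homogeneous Poisson at 1.5 sp/s
        dur = trials.trials["onset_s"].iloc[-1] + 2.0
        rates = spikes.spikes.groupby("unit_id").size() / dur
        assert abs(rates.mean() - 1.5) < 0.15

    def test_balanced_categories_required(self, planted2):
        tuning = module_tuning(planted2, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            generate_spikes(planted2, tuning, n_trials=41)

    def test_negative_gain_rejected(self, planted2):
        from micromod.synth import SpikeTuningModel

        tuning = module_tuning(planted2, seed=0)
        with pytest.raises(ValueError):
            SpikeTuningModel(
                electrode=tuning.electrode,
                module=tuning.module,
                baseline=tuning.baseline,
                gains=tuning.gains - 2.0,
                latency=tuning.latency,
                width=tuning.width,
            )

    def test_trials_all_correct_and_increasing(self, tuned_spikes):
        _, trials = tuned_spikes
        assert trials.trials["correct"].all()
        assert np.all(np.diff(trials.trials["onset_s"]) > 0)
        assert len(trials.baseline_periods) >= 2

    def test_shared_tuning_within_modules(self, planted2):
        tuning = module_tuning(planted2, gain=3.0, tuning_correlation=1.0, seed=4)
        for m in range(planted2.n_modules):
            g = tuning.gains[tuning.module == m]
            assert np.allclose(g, g[0])
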