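"""LFP cleaning chain: rejection, referencing, detrending, line noise,
artifact interpolation and block extraction."""

import numpy as np
import pytest
from scipy import stats

from micromod.layout import make_layout
from micromod.preprocess import (
    common_average_reference,
    extract_blocks,
    interpolate_artifacts,
    local_detrend,
    remove_line_noise,
    reject_bad_electrodes,
)
from micromod.session import SessionRecording


def _rec(lfp, fs=1000.0):
    n = lfp.shape[0]
    side = max(2, int(np.ceil(np.sqrt(n))))
    lay = make_layout(side, side, 0.4)
    return SessionRecording(lfp=lfp, fs=fs, layout=lay, retained_channels=np.arange(n))


def _tone_amplitude(x, fs, freq):
    T = x.size
    t = np.arange(T) / fs
    return 2 * abs(np.mean(x * np.exp(-2j * np.pi * freq * t)))


class TestRejection:
    def test_high_variance_channel_removed(self):
        rng = np.random.default_rng(0)
        lfp = rng.standard_normal((16, 5000))
        lfp[3] *= 15.0
        out, rejected = reject_bad_electrodes(_rec(lfp))
        assert rejected == [3]
        assert out.n_channels == 15

    def test_homogeneous_channels_kept(self):
        rng = np.random.default_rng(1)
        out, rejected = reject_bad_electrodes(_rec(rng.standard_normal((10, 5000))))
        assert rejected == []

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        lfp = rng.standard_normal((12, 5000))
        lfp[0] *= 20.0
        out, _ = reject_bad_electrodes(_rec(lfp))
        out2, rejected2 = reject_bad_electrodes(out)
        assert rejected2 == []


class TestReference:
    def test_common_offset_removed(self):
        lfp = np.full((4, 100), 3.7)
        out = common_average_reference(_rec(lfp))
        assert np.allclose(out.lfp, 0.0)

    def test_zero_mean_every_sample(self):
        rng = np.random.default_rng(0)
        out = common_average_reference(_rec(rng.standard_normal((6, 500))))
        assert np.allclose(out.lfp.mean(axis=0), 0.0, atol=1e-12)

    def test_impulse_split(self):
        n = 5
        lfp = np.zeros((n, 10))
        lfp[2, 4] = 1.0
        out = common_average_reference(_rec(lfp))
        assert np.isclose(out.lfp[2, 4], (n - 1) / n)
        assert np.allclose(np.delete(out.lfp[:, 4], 2), -1 / n)

    def test_single_channel_error(self):
        with pytest.raises(ValueError):
            common_average_reference(_rec(np.zeros((1, 100))))


class TestDetrend:
    def test_slow_tone_attenuated(self):
        fs, T = 1000.0, 20000
        t = np.arange(T) / fs
        x = np.sin(2 * np.pi * 0.5 * t)[None, :]
        out = local_detrend(_rec(x, fs))
        ratio = _tone_amplitude(out.lfp[0], fs, 0.5) / _tone_amplitude(x[0], fs, 0.5)
        assert 20 * np.log10(ratio) < -10

    def test_fast_tone_preserved(self):
        fs, T = 1000.0, 20000
        t = np.arange(T) / fs
        x = np.sin(2 * np.pi * 40 * t)[None, :]
        out = local_detrend(_rec(x, fs))
        ratio = _tone_amplitude(out.lfp[0], fs, 40.0) / _tone_amplitude(x[0], fs, 40.0)
        assert abs(ratio - 1) < 0.05

    def test_constant_becomes_zero(self):
        out = local_detrend(_rec(np.full((2, 5000), 2.5)))
        assert np.allclose(out.lfp, 0.0, atol=1e-9)

    def test_window_longer_than_recording_errors(self):
        with pytest.raises(ValueError):
            local_detrend(_rec(np.zeros((2, 100))), window=1.0)


class TestLineNoise:
    def test_60hz_tone_removed(self):
        fs, T = 1000.0, 30000
        rng = np.random.default_rng(0)
        t = np.arange(T) / fs
        x = 0.05 * np.sin(2 * np.pi * 60 * t) + 0.001 * rng.standard_normal(T)
        out = remove_line_noise(_rec(x[None, :], fs))
        assert _tone_amplitude(out.lfp[0], fs, 60.0) < 1e-3  # < 1 uV residual

    def test_harmonic_removed(self):
        fs, T = 1000.0, 30000
        t = np.arange(T) / fs
        x = 0.05 * np.sin(2 * np.pi * 180 * t + 0.3)
        out = remove_line_noise(_rec(x[None, :], fs))
        assert _tone_amplitude(out.lfp[0], fs, 180.0) < 1e-3

    def test_broadband_untouched(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 30000))
        out = remove_line_noise(_rec(x))
        for ch in range(2):
            assert np.corrcoef(x[ch], out.lfp[ch])[0, 1] > 0.999

    def test_sample_count_preserved(self):
        x = np.random.default_rng(2).standard_normal((2, 12345))
        out = remove_line_noise(_rec(x))
        assert out.n_samples == 12345


class TestInterpolation:
    def test_spike_artifact_flagged_and_bounded(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 3000))
        x[0, 1500] = 50.0
        out, mask = interpolate_artifacts(x, fs=1000.0)
        assert mask[0, 1500]
        assert mask[0].sum() >= 11  # +-5 samples around the artifact
        lo, hi = x[0, 1480:1494].min(), x[0, 1480:1494].max()
        assert out[0, 1495:1506].max() < 10.0  # artifact magnitude gone

    def test_gaussian_flag_rate_matches_threshold_rule(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((1, 200000))
        out, mask = interpolate_artifacts(x, fs=1000.0)
        med = np.median(x)
        mad = np.median(np.abs(x - med)) * 1.4826
        exceed = np.abs(x[0] - med) > 4 * mad  # the threshold rule itself
        # expected exceedance ~ 2*Phi(-4) ~ 6e-5 for Gaussian data
        assert abs(exceed.mean() - 2 * stats.norm.sf(4)) < 3e-4
        # mask covers exactly the exceedances padded by 5 samples
        grow = np.zeros_like(exceed)
        for i in np.nonzero(exceed)[0]:
            grow[max(0, i - 5) : i + 6] = True
        assert np.array_equal(mask[0], grow)

    def test_constant_clip_untouched(self):
        x = np.full((1, 2000), 1.0)
        out, mask = interpolate_artifacts(x, fs=1000.0)
        assert not mask.any()
        assert np.array_equal(out, x)


class TestExtractBlocks:
    def test_artifact_pushes_window_later(self):
        rng = np.random.default_rng(0)
        lfp = 0.01 * rng.standard_normal((8, 30000))
        lfp[:, 0:10000:500] = 5.0  # artifacts in seconds 0-10 of the clip
        rec = _rec(lfp)
        bset = extract_blocks(rec, n_clips=1, clip_len=30.0, block_len=5.0)
        # artifacts (with their interpolation pads) end just after 9.5 s
        assert bset.block_starts[0] >= 9.5

    def test_clean_clip_takes_first_window(self):
        # a pure sinusoid never exceeds the MAD threshold: zero artifacts
        t = np.arange(30000) / 1000.0
        rec = _rec(np.tile(np.sin(2 * np.pi * 10 * t), (8, 1)))
        bset = extract_blocks(rec, n_clips=1, clip_len=30.0, block_len=5.0)
        assert bset.block_starts[0] == 0.0

    def test_counts_and_shapes(self):
        rng = np.random.default_rng(2)
        rec = _rec(0.01 * rng.standard_normal((8, 4 * 10000)))
        bset = extract_blocks(rec, n_clips=4, clip_len=10.0, block_len=2.0)
        assert bset.n_blocks == 4
        assert all(b.shape == (8, 2000) for b in bset.blocks)

    def test_short_recording_error_lists_requirement(self):
        rec = _rec(np.zeros((8, 1000)))
        with pytest.raises(ValueError, match="600"):
            extract_blocks(rec, n_clips=20, clip_len=30.0, block_len=5.0)
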