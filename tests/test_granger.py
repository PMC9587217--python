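"""Conditional Granger causality: VAR fitting, time/spectral GC,
significance, band aggregation."""

import numpy as np
import pytest

from micromod.granger import (
    DEFAULT_BANDS,
    SpectralGCResult,
    band_contributions,
    conditional_gc_matrix,
    fit_var,
    gc_significance,
    spectral_conditional_gc,
    var_autocovariance,
    whittle_var,
)
from micromod.session import BlockSet
from micromod.synth import VARGroundTruth, simulate_var


def _blocks_from(truth, n_samples, n_blocks, seed, fs=1000.0):
    rng = np.random.default_rng(seed)
    return BlockSet(
        blocks=[simulate_var(truth, n_samples, rng) for _ in range(n_blocks)], fs=fs
    )


def _population_bivariate_F(a_self, c, b_self, sig=1.0, n_freq=20001):
    """Oracle: population GC y->x for x_t = a x_{t-1} + c y_{t-1},
    y_t = b y_{t-1}, via the Kolmogorov (Szego) formula for the reduced
    innovation variance of the x marginal."""
    w = np.linspace(0, np.pi, n_freq)
    z = np.exp(-1j * w)
    hxx = 1.0 / (1 - a_self * z)
    hxy = c * z / ((1 - a_self * z) * (1 - b_self * z))
    Sxx = sig * (np.abs(hxx) ** 2 + np.abs(hxy) ** 2)
    red_var = np.exp(np.trapezoid(np.log(Sxx), w) / np.pi)
    return np.log(red_var / sig)


class TestFitVar:
    def test_recovers_generating_coefficients(self):
        rng = np.random.default_rng(0)
        coeffs = rng.standard_normal((2, 4, 4)) * 0.15
        coeffs[0] += np.eye(4) * 0.4
        truth = VARGroundTruth(order=2, coeffs=coeffs, noise_cov=np.eye(4) * 0.01)
        blocks = _blocks_from(truth, 5000, 20, seed=1)
        model = fit_var(blocks, 2)
        rmse = np.sqrt(np.mean((model.coeffs - coeffs) ** 2))
        assert rmse < 0.05

    def test_white_noise_coefficients_near_zero(self, white_blocks):
        model = fit_var(white_blocks, 2)
        bound = 3 / np.sqrt(model.n_effective)
        assert np.percentile(np.abs(model.coeffs), 95) < bound

    def test_order_zero_rejected(self, white_blocks):
        with pytest.raises(ValueError):
            fit_var(white_blocks, 0)

    def test_whittle_recovers_var_from_autocovariance(self):
        rng = np.random.default_rng(3)
        coeffs = rng.standard_normal((2, 3, 3)) * 0.2
        coeffs[0] += np.eye(3) * 0.3
        sig = np.eye(3) * 0.5 + 0.1
        G = var_autocovariance(coeffs, sig, 10)
        A, S = whittle_var(G, 2)
        assert np.allclose(A, coeffs, atol=1e-10)
        assert np.allclose(S, sig, atol=1e-10)


@pytest.fixture(scope="module")
def embedded_bivariate():
    """x <- y coupling embedded among independent channels."""
    n = 6
    coeffs = np.zeros((1, n, n))
    np.fill_diagonal(coeffs[0], 0.3)
    coeffs[0, 0, 0] = 0.5
    coeffs[0, 1, 1] = 0.7
    coeffs[0, 0, 1] = 0.4  # y (ch 1) -> x (ch 0)
    truth = VARGroundTruth(order=1, coeffs=coeffs, noise_cov=np.eye(n))
    return truth, _blocks_from(truth, 10000, 10, seed=7)


class TestConditionalGC:
    def test_matches_analytic_population_value(self, embedded_bivariate):
        truth, blocks = embedded_bivariate
        F = conditional_gc_matrix(blocks, order=8).F
        expect = _population_bivariate_F(0.5, 0.4, 0.7)
        assert abs(F[0, 1] - expect) / expect < 0.05
        assert F[1, 0] < 0.001  # no reverse causation

    def test_scale_invariance(self, embedded_bivariate):
        _, blocks = embedded_bivariate
        F1 = conditional_gc_matrix(blocks, 4).F
        scaled = BlockSet(
            blocks=[b * np.array([3.0, 0.2, 1, 1, 1, 1])[:, None] for b in blocks.blocks],
            fs=blocks.fs,
        )
        F2 = conditional_gc_matrix(scaled, 4).F
        assert np.allclose(F1, F2, atol=1e-10)

    def test_chain_common_dependency_suppressed(self):
        """z -> y -> x with no direct z->x: the conditional F suppresses
        the indirect path (significance rate at chance across seeds)."""
        n = 3
        hits = 0
        for seed in range(10):
            coeffs = np.zeros((1, n, n))
            np.fill_diagonal(coeffs[0], 0.4)
            coeffs[0, 1, 2] = 0.5  # z->y
            coeffs[0, 0, 1] = 0.5  # y->x
            truth = VARGroundTruth(order=1, coeffs=coeffs, noise_cov=np.eye(n))
            blocks = _blocks_from(truth, 5000, 6, seed=100 + seed)
            sig = gc_significance(conditional_gc_matrix(blocks, 3))
            hits += bool(sig.mask[0, 2])
        assert hits <= 1

    def test_nonnegative_and_zero_diagonal(self, var_blocks):
        F = conditional_gc_matrix(var_blocks, 4).F
        assert np.all(F >= 0)
        assert np.all(np.diag(F) == 0)

    def test_consistency_with_sample_size(self, embedded_bivariate):
        truth, _ = embedded_bivariate
        expect = _population_bivariate_F(0.5, 0.4, 0.7)
        errs = []
        for n_samples in (2000, 20000):
            blocks = _blocks_from(truth, n_samples, 5, seed=13)
            F = conditional_gc_matrix(blocks, 6).F
            errs.append(abs(F[0, 1] - expect))
        assert errs[1] < errs[0]


class TestSignificance:
    def test_all_zero_F_gives_empty_mask(self, white_blocks):
        gcm = conditional_gc_matrix(white_blocks, 2)
        gcm.F[:] = 0.0
        sig = gc_significance(gcm)
        assert sig.mask.sum() == 0

    def test_strong_edge_retained(self):
        coeffs = np.zeros((1, 4, 4))
        np.fill_diagonal(coeffs[0], 0.3)
        coeffs[0, 0, 1] = 0.6
        truth = VARGroundTruth(order=1, coeffs=coeffs, noise_cov=np.eye(4))
        blocks = _blocks_from(truth, 4000, 5, seed=3)
        sig = gc_significance(conditional_gc_matrix(blocks, 2))
        assert sig.mask[0, 1]
        assert sig.F[0, 1] > 0

    def test_thresholded_entries_exactly_zero(self, white_blocks):
        sig = gc_significance(conditional_gc_matrix(white_blocks, 2))
        assert np.all(sig.F[~sig.mask] == 0)


@pytest.fixture(scope="module")
def sgc_and_F(var_blocks):
    sgc = spectral_conditional_gc(var_blocks, 4, n_freq=512)
    F = conditional_gc_matrix(var_blocks, 4, reduced="model").F
    return sgc, F


class TestSpectralGC:
    def test_integral_identity(self, sgc_and_F):
        sgc, F = sgc_and_F
        integral = np.trapezoid(sgc.f, sgc.freq_grid, axis=2) * 2 / sgc.fs
        off = ~np.eye(F.shape[0], dtype=bool)
        rel = np.abs(integral - F)[off] / np.maximum(F[off], 1e-12)
        assert np.median(rel) < 0.02

    def test_spectra_nonnegative(self, sgc_and_F):
        sgc, _ = sgc_and_F
        assert np.all(sgc.f >= 0)

    def test_gamma_coupling_peaks_in_gamma_band(self, planted2, var_truth, var_blocks):
        """Within-module couplings are gamma-shaped by construction, so
        their GC spectra should peak inside 70-150 Hz."""
        sgc = spectral_conditional_gc(var_blocks, 4, n_freq=512)
        labels = planted2.labels
        w = np.abs(var_truth.coeffs).sum(axis=0)
        np.fill_diagonal(w, 0)
        same = labels[:, None] == labels[None, :]
        coupled = same & (w > 0) & ~np.eye(16, dtype=bool)
        mean_spec = sgc.f[coupled].mean(axis=0)
        peak = sgc.freq_grid[np.argmax(mean_spec)]
        assert 70 <= peak <= 150

    def test_independent_channels_near_flat_zero(self, white_blocks):
        sgc = spectral_conditional_gc(white_blocks, 2, n_freq=128)
        off = ~np.eye(6, dtype=bool)
        assert np.nanmax(sgc.f[off]) < 0.05


class TestBandContributions:
    def _flat_sgc(self):
        grid = np.linspace(0, 500, 501)
        f = np.full((2, 2, 501), 1.0 / 500)
        for i in range(2):
            f[i, i] = 0
        return SpectralGCResult(freq_grid=grid, f=f, fs=1000.0)

    def test_flat_unit_area_spectrum(self):
        band = band_contributions(self._flat_sgc(), normalize=False)
        for name in DEFAULT_BANDS:
            assert np.allclose(band.values[name][0, 1], 1 / 500)

    def test_normalization_unit_area(self, var_blocks):
        sgc = spectral_conditional_gc(var_blocks, 4, n_freq=256)
        spectra = sgc.f.copy()
        area = np.trapezoid(spectra, sgc.freq_grid, axis=2)
        norm = band_contributions(sgc, normalize=True)
        # reconstruct: normalized band value * area ~ raw band value
        raw = band_contributions(sgc, normalize=False)
        nz = area > 1e-8
        k = "gamma"
        assert np.allclose(
            norm.values[k][nz] * area[nz], raw.values[k][nz], rtol=1e-6
        )

    def test_within_module_gamma_share_higher(self, planted2, var_blocks):
        sgc = spectral_conditional_gc(var_blocks, 4, n_freq=256)
        band = band_contributions(sgc, normalize=True)
        labels = planted2.labels
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(16, dtype=bool)
        g = band.values["gamma"]
        assert g[same & off].mean() > g[~same].mean()

    def test_band_outside_grid_errors(self):
        sgc = self._flat_sgc()
        with pytest.raises(ValueError):
            band_contributions(sgc, bands={"hf": (400.0, 600.0)})
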