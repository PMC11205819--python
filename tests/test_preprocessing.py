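import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ramansip.preprocessing import (
    PreprocessParams,
    als_baseline,
    average_spectra,
    correct_baseline,
    crop,
    normalize,
    preprocess_ramanome,
    remove_spikes,
    smooth_savgol,
    subtract_blank,
)
from ramansip.peak_fitting import fit_band
from ramansip.spectra_io import Ramanome, Spectrum
from ramansip.synthetic import default_config, simulate_ramanome, simulate_spectrum

from conftest import make_single_band_config

DISABLED = PreprocessParams(
    savgol_window=None,
    baseline_method="none",
    spike_zscore=None,
    normalize_mode="none",
    crop_range=None,
    subtract_blanks=False,
)


def flat_spectrum(n=100, value=1.0, lo=400.0):
    x = lo + np.arange(n, dtype=float)
    return Spectrum(x, np.full(n, value))


class TestSavgol:
    def test_reproduces_low_order_polynomial(self):
        x = 300.0 + np.arange(200.0)
        y = 2.0 + 0.03 * x - 1e-5 * x**2
        out = smooth_savgol(Spectrum(x, y), PreprocessParams())
        np.testing.assert_allclose(out.intensity[5:-5], y[5:-5], rtol=1e-8)

    def test_constant_unchanged(self):
        s = flat_spectrum()
        out = smooth_savgol(s, PreprocessParams())
        np.testing.assert_allclose(out.intensity, s.intensity)

    def test_reduces_noise_variance(self):
        rng = np.random.default_rng(0)
        x = 300.0 + np.arange(500.0)
        s = Spectrum(x, rng.normal(0.0, 1.0, 500) + 10.0)
        out = smooth_savgol(s, PreprocessParams())
        assert np.var(out.intensity) < np.var(s.intensity)

    def test_non_uniform_axis_rejected(self):
        x = np.array([400.0, 401.0, 403.0, 404.0, 405.0, 406.0, 407.0, 408.0,
                      409.0, 410.0, 411.0])
        with pytest.raises(ValueError, match="resample"):
            smooth_savgol(Spectrum(x, np.ones(11)), PreprocessParams())

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            PreprocessParams(savgol_window=10)


class TestRemoveSpikes:
    def test_spike_free_is_identity(self):
        s = simulate_spectrum(make_single_band_config(noise_sd=0.02, seed=1), 0)
        out = remove_spikes(s, 8.0)
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_single_spike_removed_close_to_truth(self):
        noise_sd = 0.02
        cfg = make_single_band_config(noise_sd=noise_sd, seed=2)
        truth = simulate_spectrum(make_single_band_config(seed=2), 0)
        s = simulate_spectrum(cfg, 0)
        y = s.intensity.copy()
        k = 30
        y[k] += 30 * noise_sd
        out = remove_spikes(s.with_intensity(y), 8.0)
        assert abs(out.intensity[k] - truth.intensity[k]) < 5 * noise_sd

    def test_two_adjacent_spikes_both_removed(self):
        noise_sd = 0.02
        s = simulate_spectrum(make_single_band_config(noise_sd=noise_sd, seed=3), 0)
        y = s.intensity.copy()
        y[40] += 25 * noise_sd
        y[41] += 35 * noise_sd
        out = remove_spikes(s.with_intensity(y), 8.0)
        assert abs(out.intensity[40] - s.intensity[40]) < 5 * noise_sd
        assert abs(out.intensity[41] - s.intensity[41]) < 5 * noise_sd

    def test_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="5"):
            remove_spikes(Spectrum([1.0, 2.0, 3.0], [0.0, 1.0, 0.0]), 8.0)


class TestSubtractBlank:
    def test_self_subtraction_gives_zero(self):
        s = flat_spectrum(value=3.0)
        out = subtract_blank(s, [s])
        np.testing.assert_allclose(out.intensity, 0.0)

    def test_empty_blank_list_is_identity(self):
        s = flat_spectrum()
        out = subtract_blank(s, [])
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_axis_mismatch_rejected(self):
        s = flat_spectrum(lo=400.0)
        b = flat_spectrum(lo=500.0)
        with pytest.raises(ValueError, match="axis"):
            subtract_blank(s, [b])

    def test_residual_background_is_centred_on_zero(self, ruegeria_ref):
        """Cell minus mean blank leaves only noise in a band-free window."""
        cfg = default_config(ruegeria_ref, seed=5, noise_sd=0.05)
        ram = simulate_ramanome(cfg, n_cells=1, n_blanks=4)
        out = subtract_blank(ram.spectra[0], ram.blanks)
        x = out.wavenumber_cm1
        window = (x > 2000) & (x < 2800)  # no Ruegeria bands in this range
        resid = out.intensity[window]
        se = 0.05 * np.sqrt(1 + 1 / 4) / np.sqrt(window.sum())
        assert abs(resid.mean()) < 3 * se


class TestBaseline:
    def test_pure_baseline_removed_below_one_percent(self):
        x = 300.0 + np.arange(2000.0)
        t = (x - x[0]) / (x[-1] - x[0])
        y = 0.5 + 0.4 * t - 0.2 * t**2 + 0.6 * np.exp(-(x - x[0]) / 1000.0)
        out = correct_baseline(Spectrum(x, y), PreprocessParams())
        assert np.max(np.abs(out.intensity)) < 0.01 * np.max(y)

    def test_zero_spectrum_stays_zero(self):
        s = Spectrum(300.0 + np.arange(100.0), np.zeros(100))
        out = correct_baseline(s, PreprocessParams())
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-9)

    def test_correction_moves_fitted_center_by_under_half_wavenumber(self):
        cfg = make_single_band_config(center=1000.0, baseline=True,
                                      grid=(900.0, 1100.0, 1.0))
        s = simulate_spectrum(cfg, 0)
        before = fit_band(s, 1000.0).center_cm1
        after = fit_band(correct_baseline(s, PreprocessParams()), 1000.0).center_cm1
        assert abs(after - before) < 0.5

    def test_invalid_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            als_baseline(np.ones(50), p=1.5)

    def test_polynomial_method_also_flattens(self):
        x = 300.0 + np.arange(1000.0)
        t = (x - x[0]) / (x[-1] - x[0])
        y = 1.0 + t - 0.5 * t**2
        params = PreprocessParams(baseline_method="poly", poly_degree=5)
        out = correct_baseline(Spectrum(x, y), params)
        assert np.max(np.abs(out.intensity)) < 0.01 * np.max(y)


class TestNormalize:
    def test_area_mode_integrates_to_one(self):
        s = simulate_spectrum(make_single_band_config(baseline=True), 0)
        out = normalize(s, "area")
        assert np.trapezoid(out.intensity, out.wavenumber_cm1) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_vector_mode_idempotent(self):
        s = simulate_spectrum(make_single_band_config(), 0)
        once = normalize(s, "vector")
        twice = normalize(once, "vector")
        np.testing.assert_allclose(twice.intensity, once.intensity, rtol=1e-12)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        s = simulate_spectrum(make_single_band_config(baseline=True), 0)
        direct = normalize(s, "area")
        scaled = normalize(s.with_intensity(s.intensity * scale), "area")
        np.testing.assert_allclose(scaled.intensity, direct.intensity, rtol=1e-9)

    def test_zero_spectrum_rejected(self):
        s = Spectrum(300.0 + np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError, match="zero"):
            normalize(s, "area")


class TestCrop:
    def test_bounds_honoured(self):
        x = 200.0 + np.arange(3801.0)
        s = Spectrum(x, np.ones_like(x))
        out = crop(s, 300.0, 3500.0)
        assert out.wavenumber_cm1.min() >= 300.0
        assert out.wavenumber_cm1.max() <= 3500.0

    def test_full_range_is_identity(self):
        s = flat_spectrum()
        out = crop(s, s.wavenumber_cm1[0], s.wavenumber_cm1[-1])
        assert len(out) == len(s)

    def test_fractional_bounds(self):
        x = np.arange(390.0, 3545.0)
        s = Spectrum(x, np.ones_like(x))
        out = crop(s, 394.11, 3540.90)
        assert out.wavenumber_cm1[0] == 395.0
        assert out.wavenumber_cm1[-1] == 3540.0

    def test_empty_result_rejected(self):
        s = flat_spectrum()
        with pytest.raises(ValueError, match="no points"):
            crop(s, 10.0, 20.0)


class TestAverage:
    def test_average_of_identical_is_identity(self):
        s = flat_spectrum(value=2.0)
        ram = Ramanome([s, s, s], {})
        np.testing.assert_allclose(average_spectra(ram).intensity, s.intensity)

    def test_average_of_opposites_is_zero(self):
        s = flat_spectrum(value=2.0)
        neg = s.with_intensity(-s.intensity)
        ram = Ramanome([s, neg], {})
        np.testing.assert_allclose(average_spectra(ram).intensity, 0.0)

    def test_averaging_shrinks_noise_variance(self, ruegeria_ref):
        cfg = default_config(ruegeria_ref, seed=6, noise_sd=0.05)
        ram = simulate_ramanome(cfg, n_cells=20, n_blanks=0)
        avg = average_spectra(ram)
        x = avg.wavenumber_cm1
        window = (x > 2000) & (x < 2800)
        # detrend the smooth baseline before measuring residual variance
        coeffs = np.polyfit(x[window], avg.intensity[window], 2)
        resid = avg.intensity[window] - np.polyval(coeffs, x[window])
        expected = 0.05**2 / 20
        assert expected / 2 < np.var(resid) < expected * 2


class TestChain:
    def test_all_stages_disabled_is_identity(self, ruegeria_ref):
        ram = simulate_ramanome(default_config(ruegeria_ref, seed=7), n_cells=2)
        out = preprocess_ramanome(ram, DISABLED)
        np.testing.assert_array_equal(
            out.spectra[0].intensity, ram.spectra[0].intensity
        )

    def test_deterministic_and_pure(self, ruegeria_ref):
        ram = simulate_ramanome(default_config(ruegeria_ref, seed=8), n_cells=2)
        before = ram.spectra[0].intensity.copy()
        a = preprocess_ramanome(ram)
        b = preprocess_ramanome(ram)
        np.testing.assert_array_equal(a.spectra[0].intensity, b.spectra[0].intensity)
        np.testing.assert_array_equal(ram.spectra[0].intensity, before)

    def test_stage_errors_name_the_cell(self):
        x = np.arange(400.0, 412.0)
        s = Spectrum(x, np.ones(12), {"cell_id": "bad_cell"})
        ram = Ramanome([s], {})
        with pytest.raises(ValueError, match="bad_cell"):
            preprocess_ramanome(ram, PreprocessParams(crop_range=(3000.0, 3500.0)))
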