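import numpy as np
import pytest

from afspectra.cube_io import SpectralCube, WavelengthAxis
from afspectra.errors import CalibrationError
from afspectra.spectral_fit import (
    CalibrationRecord,
    apply_calibration,
    calibrate_session,
    fit_mean_spectrum,
    fit_pixels,
    fit_spectrum,
)
from afspectra.synthetic_scene import (
    FluorophoreSpec,
    emission_spectrum,
    render_microspheres,
    render_section,
    SceneConfig,
    BRM,
    LIPOFUSCIN,
)


def _cube_from_spectra(spectra, axis):
    """Stack a list of per-pixel spectra into a 1 x N cube."""
    arr = np.round(np.asarray(spectra)).astype(np.uint16)[np.newaxis, :, :]
    return SpectralCube(arr, axis)


class TestFitSpectrum:
    def test_exact_parabola_vertex_to_machine_precision(self, axis):
        lam = axis.wavelengths
        y = -((lam - 550.0) ** 2) + 10000.0
        fit = fit_spectrum(y, axis)
        assert fit.valid
        assert fit.peak_nm == pytest.approx(550.0, abs=1e-9)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_monotone_spectrum_is_invalid(self, axis):
        fit = fit_spectrum(np.linspace(0, 2000, axis.n_channels), axis)
        assert not fit.valid

    def test_constant_spectrum_invalid_without_exception(self, axis):
        fit = fit_spectrum(np.full(axis.n_channels, 800.0), axis)
        assert not fit.valid
        fit0 = fit_spectrum(np.zeros(axis.n_channels), axis)
        assert not fit0.valid and np.isnan(fit0.peak_nm)

    def test_gaussian_peak_recovered_within_1nm(self, axis):
        vec = emission_spectrum(FluorophoreSpec("m", 546.0, amplitude=2000.0), axis)
        fit = fit_spectrum(vec, axis)
        assert abs(fit.peak_nm - 546.0) < 1.0

    def test_shift_equivariance(self, axis):
        rng = np.random.default_rng(0)
        y = emission_spectrum(FluorophoreSpec("m", 560.0, amplitude=1500.0), axis)
        y = y + rng.normal(0, 20, axis.n_channels)
        delta = 7.5
        shifted = WavelengthAxis(axis.start_nm + delta, axis.step_nm, axis.n_channels)
        f0 = fit_spectrum(y, axis)
        f1 = fit_spectrum(y, shifted)
        assert f1.peak_nm - f0.peak_nm == pytest.approx(delta, abs=1e-9)

    def test_scale_invariance(self, axis):
        y = emission_spectrum(FluorophoreSpec("m", 560.0, amplitude=500.0), axis)
        f1 = fit_spectrum(y, axis)
        f2 = fit_spectrum(y * 3.7, axis)
        assert f2.peak_nm == pytest.approx(f1.peak_nm, abs=1e-9)

    def test_vertex_equals_dense_grid_argmax(self, axis):
        # oracle equivalence on 1000 random valid fits at 0.01 nm resolution
        rng = np.random.default_rng(42)
        lam_grid = np.arange(axis.start_nm, axis.end_nm + 0.005, 0.01)
        n_checked = 0
        while n_checked < 1000:
            peak = rng.uniform(520, 600)
            width = rng.uniform(40, 90)
            amp = rng.uniform(300, 3000)
            y = amp * np.exp(-((axis.wavelengths - peak) ** 2) / (2 * width**2))
            y = y + rng.normal(0, amp * 0.02, axis.n_channels)
            fit = fit_spectrum(y, axis)
            if not fit.valid:
                continue
            poly = fit.a * lam_grid**2 + fit.b * lam_grid + fit.c
            grid_peak = lam_grid[np.argmax(poly)]
            assert abs(grid_peak - fit.peak_nm) <= 0.0051
            n_checked += 1


class TestFitPixels:
    def test_uniform_region_mean_equals_single_pixel_peak(self, axis):
        spec = emission_spectrum(FluorophoreSpec("m", 560.0, amplitude=2000.0), axis)
        cube = _cube_from_spectra([spec] * 6, axis)
        res = fit_pixels(cube, np.ones((1, 6), bool))
        single = fit_spectrum(np.round(spec), axis)
        assert res.mean_peak_nm == pytest.approx(single.peak_nm, abs=1e-9)
        assert res.invalid_fraction == 0.0
        # average-then-fit agrees on identical spectra (linearity)
        mean_fit = fit_mean_spectrum(cube, np.ones((1, 6), bool))
        assert mean_fit.peak_nm == pytest.approx(single.peak_nm, abs=1e-9)

    def test_mean_skips_invalid_pixels(self, axis):
        good = emission_spectrum(FluorophoreSpec("m", 560.0, amplitude=2000.0), axis)
        bad = np.linspace(0, 2000, axis.n_channels)  # monotone -> invalid
        cube = _cube_from_spectra([good, bad], axis)
        res = fit_pixels(cube, np.ones((1, 2), bool))
        assert res.n_valid == 1
        assert res.invalid_fraction == pytest.approx(0.5)
        assert res.mean_peak_nm == pytest.approx(
            fit_spectrum(np.round(good), axis).peak_nm, abs=1e-9
        )

    def test_all_invalid_mask_yields_nan_mean(self, axis):
        bad = np.linspace(0, 2000, axis.n_channels)
        cube = _cube_from_spectra([bad, bad], axis)
        res = fit_pixels(cube, np.ones((1, 2), bool))
        assert np.isnan(res.mean_peak_nm) and res.n_valid == 0

    def test_empty_mask_raises(self, random_cube):
        with pytest.raises(ValueError):
            fit_pixels(random_cube, np.zeros(random_cube.shape[:2], bool))

    def test_noisy_parameter_recovery_mean_error_below_2nm(self):
        # seeded noisy renders: average absolute peak error across components
        errs = []
        for seed in range(8):
            cube, gt = render_section(SceneConfig(shape=(160, 160), seed=seed))
            for label, name in ((BRM, "brm"), (LIPOFUSCIN, "lipofuscin")):
                fit = fit_pixels(cube, gt.mask(label))
                errs.append(abs(fit.mean_peak_nm - gt.true_peaks[name]))
        assert np.mean(errs) < 2.0


class TestFitMeanSpectrum:
    def test_equal_mixture_peaks_between_components(self, axis):
        a = emission_spectrum(FluorophoreSpec("brm", 549.0, amplitude=2000.0), axis)
        b = emission_spectrum(FluorophoreSpec("lp", 575.0, amplitude=2000.0), axis)
        cube = _cube_from_spectra([a, b], axis)
        fit = fit_mean_spectrum(cube, np.ones((1, 2), bool))
        assert 549.0 < fit.peak_nm < 575.0


class TestCalibration:
    def test_offset_arithmetic(self):
        rec = CalibrationRecord("s", 548.0, 550.0, reference_nm=546.0)
        assert rec.offset_nm == pytest.approx(546.0 - 549.0)
        assert apply_calibration(570.0, rec) == pytest.approx(567.0)

    def test_zero_offset_is_identity(self):
        rec = CalibrationRecord("s", 546.0, 546.0)
        assert apply_calibration(571.3, rec) == 571.3

    def test_zero_drift_offset_near_zero(self, microsphere_field):
        cube, _ = microsphere_field
        rec = calibrate_session(cube, cube)
        assert abs(rec.offset_nm) < 1.0

    def test_asymmetric_session_drift_uses_mean_rule(self):
        s, _ = render_microspheres(drift_nm=2.0, seed=31)
        e, _ = render_microspheres(drift_nm=4.0, seed=32)
        rec = calibrate_session(s, e)
        assert rec.offset_nm == pytest.approx(-3.0, abs=1.0)

    def test_blank_field_raises_calibration_error(self, axis):
        blank = SpectralCube(np.zeros((32, 32, axis.n_channels), dtype=np.uint16), axis)
        with pytest.raises(CalibrationError):
            calibrate_session(blank, blank)
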