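import numpy as np
import pytest

from afspectra.cube_io import DEFAULT_AXIS
from afspectra.errors import SceneConfigError
from afspectra.spectral_fit import fit_pixels, fit_spectrum
from afspectra.synthetic_scene import (
    BRM,
    FluorophoreSpec,
    LIPOFUSCIN,
    MELANOLIPOFUSCIN,
    MICROSPHERE,
    SceneConfig,
    default_fluorophores,
    emission_spectrum,
    render_microspheres,
    render_section,
)


class TestEmissionSpectrum:
    def test_mode_at_peak_channel(self, axis):
        spec = FluorophoreSpec("microsphere", 546.0, 30.0, 2000.0)
        vec = emission_spectrum(spec, axis)
        assert axis.wavelengths[np.argmax(vec)] == 544.0 or abs(
            axis.wavelengths[np.argmax(vec)] - 546.0
        ) <= 3.0  # closest channel centre to 546 within half a step... see below
        # the channel nearest 546 nm (544 is not on the axis; centres are 496+6k)
        nearest = axis.wavelengths[np.argmin(np.abs(axis.wavelengths - 546.0))]
        assert axis.wavelengths[np.argmax(vec)] == nearest

    def test_narrow_width_approaches_one_hot(self, axis):
        spec = FluorophoreSpec("brm", 550.0, 0.5, 1000.0)  # 550 is a channel centre
        vec = emission_spectrum(spec, axis)
        assert vec[9] == pytest.approx(1000.0)
        assert np.delete(vec, 9).max() < 1e-10

    def test_quadratic_vertex_recovers_peak_at_default_width(self, axis):
        # noiseless sampled spectrum -> fitted parabola vertex within 1 nm,
        # for peaks across the component range at the default spectral width
        for peak in (546.0, 549.0, 560.0, 568.0, 575.0):
            vec = emission_spectrum(FluorophoreSpec("x", peak, amplitude=2000.0), axis)
            fit = fit_spectrum(vec, axis)
            assert fit.valid
            assert abs(fit.peak_nm - peak) < 1.0, peak


class TestRenderSection:
    def test_same_seed_is_bit_identical(self):
        cfg = SceneConfig(shape=(160, 160), seed=9)
        c1, g1 = render_section(cfg)
        c2, g2 = render_section(SceneConfig(shape=(160, 160), seed=9))
        np.testing.assert_array_equal(c1.intensities, c2.intensities)
        np.testing.assert_array_equal(g1.labels, g2.labels)

    def test_ground_truth_records_configured_peaks(self, section):
        _, gt = section
        assert gt.true_peaks["brm"] == 549.0
        assert gt.true_peaks["lipofuscin"] == 575.0

    def test_realized_area_ratio_matches_target(self):
        for ratio in (0.35, 0.5):
            _, gt = render_section(SceneConfig(seed=3, target_area_ratio=ratio))
            assert abs(gt.area_ratio - ratio) / ratio < 0.02

    def test_labels_consistent_with_geometry(self, section):
        cube, gt = section
        # BrM is a full-width horizontal band
        brm_rows = np.unique(np.nonzero(gt.mask(BRM))[0])
        assert (gt.mask(BRM)[brm_rows].sum(axis=1) == cube.shape[1]).all()
        # granules sit strictly above the band
        rpe_rows = np.nonzero(gt.rpe_mask())[0]
        assert rpe_rows.max() < brm_rows.min()
        # disjoint labels by construction; melano cores are dark -> unlabeled
        assert not (gt.mask(LIPOFUSCIN) & gt.mask(MELANOLIPOFUSCIN)).any()

    def test_noiseless_render_recovers_component_peaks(self):
        cfg = SceneConfig(shape=(160, 160), seed=4, shot_noise=False, read_noise_sd=0.0)
        cube, gt = render_section(cfg)
        for label, name in ((BRM, "brm"), (LIPOFUSCIN, "lipofuscin")):
            fit = fit_pixels(cube, gt.mask(label))
            assert fit.invalid_fraction == 0.0
            assert abs(fit.mean_peak_nm - gt.true_peaks[name]) < 1.0

    def test_read_noise_does_not_reduce_peak_variance(self):
        # monotonicity of fitted-peak dispersion in the read-noise level
        def peak_var(sd, seed):
            cfg = SceneConfig(shape=(160, 160), seed=seed, read_noise_sd=sd)
            cube, gt = render_section(cfg)
            fit = fit_pixels(cube, gt.mask(BRM))
            return np.nanvar(fit.peak_map)

        lo = np.mean([peak_var(2.0, s) for s in range(3)])
        hi = np.mean([peak_var(40.0, s) for s in range(3)])
        assert hi >= lo

    def test_zero_structures_gives_pure_noise_and_empty_masks(self):
        fl = {"background": default_fluorophores()["background"]}
        cfg = SceneConfig(shape=(64, 64), fluorophores=fl, target_area_ratio=1e9, seed=1)
        # target ratio ~inf => zero RPE pixels requested
        cube, gt = render_section(cfg)
        assert not gt.rpe_mask().any()
        assert cube.intensities.max() <= 200  # background + noise only

    def test_infeasible_geometry_raises(self):
        with pytest.raises(SceneConfigError):
            render_section(SceneConfig(shape=(64, 64), target_area_ratio=0.05, seed=0))

    def test_drusen_are_rendered_when_requested(self):
        from afspectra.synthetic_scene import DRUSEN

        cube, gt = render_section(SceneConfig(seed=6, n_drusen=3))
        assert gt.mask(DRUSEN).sum() > 0


class TestRenderMicrospheres:
    def test_drift_shifts_cube_but_not_truth(self, axis):
        c0, g0 = render_microspheres(drift_nm=0.0, seed=5, shot_noise=False, read_noise_sd=0.0)
        c3, g3 = render_microspheres(drift_nm=3.0, seed=5, shot_noise=False, read_noise_sd=0.0)
        assert g0.true_peaks["microsphere"] == g3.true_peaks["microsphere"] == 546.0
        assert g3.drift_nm == 3.0
        p0 = fit_pixels(c0, g0.mask(MICROSPHERE)).mean_peak_nm
        p3 = fit_pixels(c3, g3.mask(MICROSPHERE)).mean_peak_nm
        assert p3 - p0 == pytest.approx(3.0, abs=0.15)

    def test_single_noiseless_sphere_matches_emission_spectrum(self, axis):
        cube, gt = render_microspheres(
            n_spheres=1, seed=8, shot_noise=False, read_noise_sd=0.0
        )
        m = gt.mask(MICROSPHERE)
        spec = emission_spectrum(FluorophoreSpec("microsphere", 546.0, amplitude=3000.0), axis)
        bg = emission_spectrum(FluorophoreSpec("background", 550.0, 200.0, 20.0), axis)
        np.testing.assert_allclose(cube.mean_spectrum(m), np.round(spec + bg), atol=0.5)

    def test_requires_at_least_one_sphere(self):
        with pytest.raises(SceneConfigError):
            render_microspheres(n_spheres=0)


def test_scene_config_yaml_round_trip(tmp_path):
    cfg = SceneConfig(shape=(96, 96), seed=42, drift_nm=1.5)
    p = cfg.to_file(tmp_path / "scene.yaml")
    back = SceneConfig.from_file(p)
    assert back == cfg
    c1, _ = render_section(cfg)
    c2, _ = render_section(back)
    np.testing.assert_array_equal(c1.intensities, c2.intensities)
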