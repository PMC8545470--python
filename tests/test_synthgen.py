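"""Generator unit and property tests: stacking model, interface field, render."""

import numpy as np
import pytest

from nacreorder import detect, synthgen
from nacreorder.orientation import hwhm_deg_from_slope_sigma
from nacreorder.synthgen import GrowthSpec, RenderSpec


class TestThicknessProfile:
    def test_zero_noise_gives_exact_mean(self):
        p = synthgen.make_thickness_profile(
            GrowthSpec(n_layers=50, sigma_local=0.0, sigma_env=0.0, seed=1)
        )
        assert np.all(p.thickness_nm == 340.0)

    def test_iid_sd_matches_innovation_sd(self):
        # phi = 0, no environmental term: w is i.i.d. Gaussian with SD sigma_local
        p = synthgen.make_thickness_profile(
            GrowthSpec(n_layers=100_000, sigma_local=30.0, phi=0.0, sigma_env=0.0, seed=2)
        )
        assert p.thickness_nm.std() == pytest.approx(30.0, rel=0.02)
        assert p.thickness_nm.mean() == pytest.approx(340.0, rel=0.01)

    def test_seed_determinism_bit_identical(self):
        spec = GrowthSpec(n_layers=500, seed=7)
        a = synthgen.make_thickness_profile(spec).thickness_nm
        b = synthgen.make_thickness_profile(spec).thickness_nm
        assert np.array_equal(a, b)

    def test_floor_respected(self):
        p = synthgen.make_thickness_profile(
            GrowthSpec(n_layers=20_000, sigma_local=200.0, phi=0.0, sigma_env=0.0, seed=3)
        )
        assert p.thickness_nm.min() >= 50.0

    def test_cumulative_variance_grows_linearly(self):
        # paracrystal property: Var(x_{N+n} - x_N) = n * sigma_local^2 for
        # independent increments
        sigma = 25.0
        p = synthgen.make_thickness_profile(
            GrowthSpec(n_layers=50_000, sigma_local=sigma, phi=0.0, sigma_env=0.0, seed=4)
        )
        x = p.positions()
        for n in (1, 4, 16):
            v = np.var(x[n:] - x[:-n])
            assert v == pytest.approx(n * sigma**2, rel=0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_layers=0),
            dict(n_layers=10, mean_thickness=40.0),  # below floor
            dict(n_layers=10, phi=1.0),
            dict(n_layers=10, sigma_local=-1.0),
            dict(n_layers=10, floor=0.0),
            dict(n_layers=10, mean_thickness=float("nan")),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synthgen.make_thickness_profile(GrowthSpec(**kwargs))

    def test_env_exponent_recovered_by_spectral_fit(self):
        from nacreorder import spectral

        p = synthgen.make_thickness_profile(
            GrowthSpec(n_layers=2500, sigma_local=0.0, sigma_env=60.0, alpha_env=1.5, seed=5)
        )
        with pytest.warns(UserWarning):
            est = spectral.fit_powerlaw(spectral.psd(p))
        assert est.alpha == pytest.approx(1.5, abs=0.35)  # single realization


class TestInterfaceField:
    def test_zero_halfwidth_gives_flat_parallel_interfaces(self):
        p = synthgen.make_thickness_profile(GrowthSpec(n_layers=30, seed=1))
        field = synthgen.make_interface_field(
            p, RenderSpec(orientation_halfwidth=0.0, image_width=128), seed=1
        )
        assert np.allclose(np.ptp(field.y, axis=1), 0.0)

    def test_halfwidth_reproduced_by_slope_distribution(self):
        # direct slope-distribution oracle on the generated curves
        p = synthgen.make_thickness_profile(GrowthSpec(n_layers=300, seed=2))
        render = RenderSpec(
            orientation_halfwidth=15.0,
            roughness_corr_length=2000.0,
            roughness_attenuation=0.8,
            image_width=4096,
        )
        field = synthgen.make_interface_field(p, render, seed=2)
        slopes = np.diff(field.y, axis=1) / render.pixel_size
        assert hwhm_deg_from_slope_sigma(slopes.std()) == pytest.approx(15.0, abs=1.5)

    def test_attenuation_sets_adjacent_displacement_correlation(self):
        # u_{i+1} = a u_i + sqrt(1-a^2) v_i: adjacent cross-correlation -> a
        p = synthgen.make_thickness_profile(
            GrowthSpec(n_layers=200, sigma_local=0.0, sigma_env=0.0, seed=3)
        )
        render = RenderSpec(
            orientation_halfwidth=10.0,
            roughness_corr_length=300.0,
            roughness_attenuation=0.5,
            image_width=16384,
        )
        field = synthgen.make_interface_field(p, render, seed=3)
        u = field.y - field.y.mean(axis=1, keepdims=True)
        cors = [
            np.corrcoef(u[i], u[i + 1])[0, 1] for i in range(0, field.n_interfaces - 1, 5)
        ]
        assert np.mean(cors) == pytest.approx(0.5, abs=0.05)

    def test_interfaces_strictly_increasing_per_column(self):
        s = synthgen.sample_preset("early", n_layers=150, seed=4, image_width=512)
        assert np.all(np.diff(s.truth_interfaces, axis=0) > 0)

    def test_excessive_halfwidth_rejected(self):
        with pytest.raises(ValueError):
            RenderSpec(orientation_halfwidth=90.0).validate()


class TestRender:
    def test_noise_free_minima_at_sheath_centerlines(self):
        g = GrowthSpec(n_layers=40, seed=5)
        r = RenderSpec(noise_sd=0.0, blur_sd=0.0, orientation_halfwidth=0.0, image_width=33)
        s = synthgen.make_synthetic_sample(g, r)
        tr = detect.Transect(np.arange(s.image.shape[0]) * 3.0, s.image[:, 16].astype(float))
        det = detect.detect_sheaths(tr)
        truth = s.truth_interfaces[:, 16]
        assert len(det) == truth.size
        assert np.abs(det.positions - truth).max() < 3.0  # within 1 px

    def test_image_height_matches_cumulative_thickness(self):
        g = GrowthSpec(n_layers=200, seed=6)
        r = RenderSpec(orientation_halfwidth=0.0, image_width=33)
        s = synthgen.make_synthetic_sample(g, r)
        expected_px = s.truth_profile.thickness_nm.sum() / r.pixel_size
        assert s.image.shape[0] == pytest.approx(expected_px, rel=0.05)

    def test_truth_profile_equals_interface_differences(self):
        s = synthgen.sample_preset("mature", n_layers=100, seed=7, image_width=65)
        ref = s.truth_interfaces[:, s.reference_column]
        assert np.allclose(np.diff(ref), s.truth_profile.thickness_nm)

    def test_render_determinism_bit_identical(self):
        a = synthgen.sample_preset("mature", n_layers=60, seed=8, image_width=65)
        b = synthgen.sample_preset("mature", n_layers=60, seed=8, image_width=65)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.truth_interfaces, b.truth_interfaces)


@pytest.fixture(scope="module")
def base_sample():
    return synthgen.sample_preset("mature", n_layers=80, seed=9, image_width=257)


class TestDislocations:
    def test_zero_density_leaves_sample_unchanged(self, base_sample):
        out = synthgen.insert_dislocations(base_sample, density=0.0)
        assert out is base_sample

    def test_exact_count_matches_density_times_area(self, base_sample):
        px = base_sample.pixel_size
        area = (base_sample.image.shape[0] * px * 1e-9) * (
            base_sample.image.shape[1] * px * 1e-9
        )
        density = 3.0 / area  # exactly 3 expected
        out = synthgen.insert_dislocations(base_sample, density=density, seed=1)
        assert len(out.truth_defects) == 3

    def test_thinning_fraction_at_defect(self, base_sample):
        px = base_sample.pixel_size
        area = (base_sample.image.shape[0] * px * 1e-9) * (
            base_sample.image.shape[1] * px * 1e-9
        )
        out = synthgen.insert_dislocations(
            base_sample, density=1.0 / area, thinning_fraction=0.28, seed=2
        )
        assert len(out.truth_defects) == 1
        # locate the thinned layer in the ground truth: minimum local
        # thickness at the defect column = 0.72x the thickness far away
        x_nm, y_nm, _ = out.truth_defects[0]
        col = int(round(x_nm / px))
        y = out.field.y
        layer = int(np.argmin(np.abs(0.5 * (y[:-1, col] + y[1:, col]) - y_nm)))
        w_at = y[layer + 1, col] - y[layer, col]
        w_before = (
            base_sample.field.y[layer + 1, col] - base_sample.field.y[layer, col]
        )
        assert w_at / w_before == pytest.approx(0.72, rel=0.02)

    def test_negative_density_rejected(self, base_sample):
        with pytest.raises(ValueError):
            synthgen.insert_dislocations(base_sample, density=-1.0)


class TestPresets:
    def test_profile_presets_recover_stage_statistics(self):
        # generator-parameter recovery at large n: early 500 +- 300,
        # mature 340 +- 120 (clip-compensated marginals)
        for name, mean, sd in [("early", 500.0, 300.0), ("mature", 340.0, 120.0)]:
            p = synthgen.make_thickness_profile(synthgen.growth_preset(name, 100_000, seed=10))
            assert p.thickness_nm.mean() == pytest.approx(mean, rel=0.03)
            assert p.thickness_nm.std() == pytest.approx(sd, rel=0.05)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            synthgen.growth_preset("juvenile")
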