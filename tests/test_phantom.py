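"""Generator correctness: ground truth must mean what it says."""

import numpy as np
import pytest

from fiberorient.phantom import (
    PhantomSpec,
    find_inflections_numeric,
    generate_channel_pair,
    generate_section,
    generate_series,
    sample_axial_von_mises,
)


def axial_diff(a, b):
    d = np.abs(np.asarray(a) - np.asarray(b)) % 180.0
    return np.minimum(d, 180.0 - d)


class TestGenerateSection:
    def test_degenerate_von_mises_collapses_on_mean(self):
        # axial spread is ~0.5/sqrt(kappa) rad, so 1e9 keeps draws within 0.01 deg
        spec = PhantomSpec(kappa=1e9, theta_fn=lambda z: 30.0, n_sections=10, seed=1)
        _, truth = generate_section(spec, 0.5, np.random.default_rng(0))
        assert truth.fiber_angles_deg  # at least one stroke drawn
        assert np.all(axial_diff(truth.fiber_angles_deg, 30.0) < 0.01)

    def test_all_longitudinal_section_has_no_strokes(self):
        spec = PhantomSpec(longitudinal_fraction_fn=lambda z: 1.0, seed=1)
        _, truth = generate_section(spec, 0.2, np.random.default_rng(0))
        assert truth.n_transverse == 0
        assert truth.transverse_area_um2 == 0.0
        assert truth.fiber_angles_deg == []

    def test_class_counts_conserve_fiber_budget(self):
        spec = PhantomSpec(n_fibers_per_section=37, seed=4)
        for z in (0.0, 0.33, 1.0):
            _, truth = generate_section(spec, z, np.random.default_rng(2))
            assert truth.n_longitudinal + truth.n_transverse == 37

    def test_seeded_determinism(self):
        spec = PhantomSpec(seed=7)
        img1, t1 = generate_section(spec, 0.4, np.random.default_rng(7))
        img2, t2 = generate_section(spec, 0.4, np.random.default_rng(7))
        assert np.array_equal(img1, img2)
        assert t1.fiber_angles_deg == t2.fiber_angles_deg

    def test_z_domain_checked(self):
        spec = PhantomSpec()
        with pytest.raises(ValueError, match="z"):
            generate_section(spec, 1.2, np.random.default_rng(0))

    def test_invalid_pixel_size_rejected(self):
        with pytest.raises(ValueError, match="pixel_size_um"):
            generate_section(
                PhantomSpec(pixel_size_um=-1.0), 0.5, np.random.default_rng(0)
            )

    def test_axial_symmetry_of_rendering(self):
        # painting a stroke at alpha and at alpha+180 gives identical images
        from fiberorient.phantom import _paint_stroke

        a = np.zeros((64, 64))
        b = np.zeros((64, 64))
        _paint_stroke(a, 32, 32, 25.0, 40.0, 1.5, 0.8)
        _paint_stroke(b, 32, 32, 205.0, 40.0, 1.5, 0.8)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_painted_area_matches_halfmax_pixel_count(self):
        # truth areas are analytic; the half-max footprint on the image must
        # agree within the anti-aliasing tolerance
        spec = PhantomSpec(
            n_fibers_per_section=8, noise_gaussian_sd=0.0, seed=9,
            longitudinal_fraction_fn=lambda z: 0.5,
        )
        img, truth = generate_section(spec, 0.5, np.random.default_rng(3))
        painted_px = np.count_nonzero(img >= 0.4)  # half of stroke amplitude 0.8
        painted_um2 = painted_px * spec.pixel_size_um**2
        total_truth = truth.longitudinal_area_um2 + truth.transverse_area_um2
        # overlaps can only shrink the union, so allow a one-sided slack too
        assert painted_um2 == pytest.approx(total_truth, rel=0.05)


class TestGenerateSeries:
    def test_z_grid_and_section_count(self):
        spec = PhantomSpec(n_sections=11, seed=0)
        images, truth = generate_series(spec)
        assert len(images) == 11
        np.testing.assert_allclose(
            [s.z for s in truth.per_section], np.linspace(0, 1, 11)
        )

    def test_too_few_sections_refused(self):
        with pytest.raises(ValueError, match="8"):
            generate_series(PhantomSpec(n_sections=7))

    def test_series_determinism(self):
        spec = PhantomSpec(n_sections=8, seed=42)
        im1, t1 = generate_series(spec)
        im2, t2 = generate_series(spec)
        assert all(np.array_equal(a, b) for a, b in zip(im1, im2))
        assert t1.inflection_points_true == t2.inflection_points_true

    def test_sine_truth_inflection_interior_only(self):
        spec = PhantomSpec(
            n_sections=8, theta_fn=lambda z: 90 + 30 * np.sin(2 * np.pi * z), seed=0
        )
        _, truth = generate_series(spec)
        assert truth.inflection_points_true == pytest.approx([0.5], abs=1e-4)


class TestInflectionOracle:
    def test_linear_theta_has_no_isolated_roots(self):
        assert find_inflections_numeric(lambda z: 10 + 5 * z) == []
        assert find_inflections_numeric(lambda z: 42.0) == []

    def test_spline_roots_match_independent_grid_scan(self):
        from scipy.interpolate import CubicSpline

        knots = np.linspace(0, 1, 5)
        cs = CubicSpline(knots, [80.0, 110.0, 70.0, 95.0, 100.0])
        recovered = find_inflections_numeric(cs)
        zz = np.arange(0.0, 1.0 + 5e-6, 1e-5)
        d2 = cs(zz, 2)
        expected = [
            float(zz[i] - 1e-5 * d2[i] / (d2[i + 1] - d2[i]))
            for i in range(len(zz) - 1)
            if d2[i] * d2[i + 1] < 0
        ]
        assert recovered == pytest.approx(expected, abs=1e-4)


class TestAxialSampling:
    def test_uniform_axial_sd_matches_closed_form(self, rng):
        # kappa=0 is uniform on a 180-degree support: SD -> 180/sqrt(12)
        draws = sample_axial_von_mises(90.0, 0.0, 200_000, rng)
        assert draws.std() == pytest.approx(180.0 / np.sqrt(12.0), abs=0.5)

    def test_concentrated_sampling_centres_on_mean(self, rng):
        draws = sample_axial_von_mises(120.0, 8.0, 5000, rng)
        two = np.deg2rad(2 * draws)
        mean = (np.degrees(np.arctan2(np.sin(two).mean(), np.cos(two).mean())) / 2) % 180
        assert axial_diff(mean, 120.0) < 2.0


class TestChannelPair:
    def test_seeded_determinism(self):
        a = generate_channel_pair(90.0, 5.0, lambda k: k, 20, seed=3)
        b = generate_channel_pair(90.0, 5.0, lambda k: k, 20, seed=3)
        assert np.array_equal(a.channel_a, b.channel_a)
        assert np.array_equal(a.channel_b, b.channel_b)
        assert a.angles_b == b.angles_b

    def test_coupling_applied_to_channel_a(self):
        cp = generate_channel_pair(90.0, 4.0, lambda k: 2 * k, 15, seed=0)
        assert cp.kappa_a == 8.0
        assert cp.kappa_b == 4.0

    def test_non_monotone_coupling_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            generate_channel_pair(90.0, 4.0, lambda k: -k, 15, seed=0)

    @pytest.mark.parametrize(
        "kwargs", [dict(kappa_b=0.0), dict(kappa_b=-1.0), dict(n_segments=5)]
    )
    def test_invalid_inputs_rejected(self, kwargs):
        args = dict(mean_angle=90.0, kappa_b=2.0, coupling=lambda k: k,
                    n_segments=20, seed=0)
        args.update(kwargs)
        with pytest.raises(ValueError):
            generate_channel_pair(**args)
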