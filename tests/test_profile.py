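"""Profile assembly, degree-7 fitting, root extraction, transition matching."""

import numpy as np
import pytest

from fiberorient.profile import (
    EnvironmentMap,
    NerveProfile,
    SectionRecord,
    average_inflections_by_rank,
    build_profile,
    find_critical_and_inflection,
    fit_polynomial,
    match_transitions,
)


def records_from(z, y):
    return [
        SectionRecord(section_index=i, z=float(zi), corrected_mean_angle_deg=float(yi))
        for i, (zi, yi) in enumerate(zip(z, y))
    ]


def sections(angles):
    return [
        dict(section_index=i, corrected_mean_angle_deg=a) for i, a in enumerate(angles)
    ]


class TestBuildProfile:
    def test_eleven_sections_make_uniform_grid(self):
        prof = build_profile(sections(np.linspace(10, 20, 11)))
        np.testing.assert_allclose([r.z for r in prof.records], np.arange(0, 1.01, 0.1))

    def test_unusable_section_dropped_z_kept(self):
        entries = sections(np.linspace(10, 20, 11))
        entries[5]["corrected_mean_angle_deg"] = np.nan
        with pytest.warns(UserWarning, match="dropped"):
            prof = build_profile(entries, nerve_length_sections=11)
        assert len(prof.records) == 10
        assert [r.z for r in prof.records] == pytest.approx(
            [i / 10 for i in range(11) if i != 5]
        )

    def test_too_few_usable_sections_rejected(self):
        with pytest.raises(ValueError):
            build_profile(sections([10.0] * 7))


class TestFitPolynomial:
    def test_exact_cubic_reproduced(self):
        z = np.linspace(0, 1, 20)
        y = 5 - 3 * z + 2 * z**2 + 7 * z**3
        prof = fit_polynomial(build_profile(sections(y)))
        np.testing.assert_allclose(prof.polynomial()(z), y, atol=1e-6)
        np.testing.assert_allclose(prof.poly_coeffs[4:], 0.0, atol=1e-6)

    def test_constant_data_constant_fit(self):
        prof = fit_polynomial(build_profile(sections([42.0] * 15)))
        np.testing.assert_allclose(prof.poly_coeffs[1:], 0.0, atol=1e-8)
        assert prof.poly_coeffs[0] == pytest.approx(42.0)

    def test_noisy_sine_recovered_within_rms(self, rng):
        z = np.linspace(0, 1, 60)
        truth = 90 + 30 * np.sin(2 * np.pi * z)
        y = truth + rng.normal(0, 3.0, 60)
        prof = fit_polynomial(build_profile(sections(y)))
        rms = np.sqrt(np.mean((prof.polynomial()(z) - truth) ** 2))
        assert rms < 3.0

    def test_duplicate_positions_rank_deficient(self):
        recs = records_from([0.1] * 10, np.arange(10))
        prof = NerveProfile(records=recs)
        with pytest.raises(ValueError, match="rank"):
            fit_polynomial(prof)


class TestRoots:
    def test_cubic_critical_and_inflection_closed_form(self):
        # p(z) = (2z-1)^3 - 3(2z-1) on [0,1]: p' roots where (2z-1)^2 = 1,
        # p'' root at z = 1/2
        z = np.linspace(0, 1, 30)
        u = 2 * z - 1
        prof = fit_polynomial(build_profile(sections(u**3 - 3 * u)))
        prof = find_critical_and_inflection(prof)
        assert prof.critical_points == pytest.approx([0.0, 1.0], abs=1e-9)
        assert prof.inflection_points == pytest.approx([0.5], abs=1e-9)

    def test_constant_fit_has_no_roots(self):
        prof = find_critical_and_inflection(
            fit_polynomial(build_profile(sections([13.0] * 12)))
        )
        assert prof.critical_points == []
        assert prof.inflection_points == []

    def test_edge_margin_excludes_boundary_inflections(self):
        z = np.linspace(0, 1, 40)
        y = 90 + 30 * np.sin(2 * np.pi * z)  # p'' roots near 0, 0.5, 1
        prof = find_critical_and_inflection(
            fit_polynomial(build_profile(sections(y), edge_margin=0.05))
        )
        assert all(0.05 <= x <= 0.95 for x in prof.inflection_points)
        assert any(abs(x - 0.5) < 0.03 for x in prof.inflection_points)

    @pytest.mark.parametrize("trial", range(20))
    def test_random_degree7_roots_match_grid_scan(self, trial):
        rng = np.random.default_rng(trial)
        coeffs = rng.normal(0, 5, 8)
        prof = NerveProfile(records=[], poly_coeffs=coeffs, edge_margin=0.0)
        prof = find_critical_and_inflection(prof)
        p = np.polynomial.Polynomial(coeffs)
        for deriv, got in ((p.deriv(1), prof.critical_points),
                           (p.deriv(2), prof.inflection_points)):
            zz = np.arange(0.0, 1.0 + 5e-6, 1e-5)
            v = deriv(zz)
            scan = [
                float(zz[i] - 1e-5 * v[i] / (v[i + 1] - v[i]))
                for i in range(len(zz) - 1)
                if v[i] * v[i + 1] < 0
            ]
            assert len(got) == len(scan)
            assert got == pytest.approx(scan, abs=1e-4)


class TestMatchTransitions:
    def test_exact_coincidence_zero_error(self):
        prof = NerveProfile(records=[], inflection_points=[0.2, 0.6])
        m = match_transitions(prof, EnvironmentMap(transitions=[0.2, 0.6]))
        assert m.per_inflection_error == [0.0, 0.0]
        assert m.mean_error == 0.0

    def test_small_offsets_average(self):
        prof = NerveProfile(records=[], inflection_points=[0.22, 0.64])
        m = match_transitions(prof, EnvironmentMap(transitions=[0.2, 0.6]))
        assert m.per_inflection_error == pytest.approx([0.02, 0.04])
        assert m.mean_error == pytest.approx(0.03)
        assert m.mean_error_pct == pytest.approx(3.0)

    def test_tie_pairs_to_smaller_z(self):
        prof = NerveProfile(records=[], inflection_points=[0.5])
        m = match_transitions(prof, EnvironmentMap(transitions=[0.4, 0.6]))
        assert m.pairing == [(0, 0)]

    def test_empty_inputs_rejected(self):
        prof = NerveProfile(records=[], inflection_points=[])
        with pytest.raises(ValueError):
            match_transitions(prof, EnvironmentMap(transitions=[0.5]))

    def test_environment_map_validation(self):
        with pytest.raises(ValueError):
            EnvironmentMap(transitions=[0.5, 0.5])
        with pytest.raises(ValueError):
            EnvironmentMap(transitions=[0.0, 0.5])

    def test_environment_map_csv_reader(self, tmp_path):
        p = tmp_path / "env.csv"
        p.write_text("z,label_before,label_after\n0.6,bone,muscle\n0.3,brain,bone\n")
        env = EnvironmentMap.from_csv(p)
        assert env.transitions == [0.3, 0.6]
        assert env.labels == ["brain->bone", "bone->muscle"]


def test_rank_order_averaging_across_nerves():
    lists = [[0.2, 0.5, 0.8], [0.3, 0.45, 0.85], [0.25, 0.55]]
    got = average_inflections_by_rank(lists)
    assert got == pytest.approx([0.25, 0.5, 0.825])
    assert average_inflections_by_rank([]) == []
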