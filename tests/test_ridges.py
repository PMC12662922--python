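"""Subpixel ridge detector: geometry, thresholds, CSV round trip."""

import io
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberorient.ridges import (
    RidgeContour,
    RidgeParams,
    contour_to_csv,
    detect_ridges,
    read_ridge_csv,
)
from tests.conftest import centerline_errors, render_line

PAPER_PARAMS = RidgeParams()  # sigma 1.2, thresholds 0/3.74, min length 2, cap 200


class TestRidgeParams:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            RidgeParams(lower_threshold=5.0, upper_threshold=1.0)

    def test_sigma_derived_from_line_width_when_absent(self):
        p = RidgeParams(sigma=None, line_width=6.0)
        assert p.sigma == pytest.approx(6.0 / (2 * np.sqrt(3)) + 0.5)

    def test_contour_needs_two_points(self):
        with pytest.raises(ValueError):
            RidgeContour(0, np.array([[1.0, 2.0]]))

    def test_length_at_least_chord(self, rng):
        pts = rng.random((10, 2)) * 50
        c = RidgeContour(0, pts)
        chord = np.hypot(*(pts[-1] - pts[0]))
        assert c.length_px >= chord - 1e-12


class TestDetectRidges:
    def test_blank_image_yields_nothing(self):
        assert detect_ridges(np.zeros((64, 64)), PAPER_PARAMS) == []

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError, match="2-D"):
            detect_ridges(np.zeros((4, 4, 4)), PAPER_PARAMS)

    def test_single_line_single_accurate_contour(self):
        img = render_line(30.0, fwhm_px=3.0)
        contours = detect_ridges(img, PAPER_PARAMS)
        assert len(contours) == 1
        c = contours[0]
        errs = centerline_errors(c.points, (64, 64), 30.0)
        assert np.all(errs < 0.5)
        dx, dy = c.end_point - c.start_point
        angle = np.degrees(np.arctan2(dy, dx)) % 180
        assert min(abs(angle - 30), 180 - abs(angle - 30)) < 1.0

    def test_parallel_lines_stay_separate(self):
        from fiberorient.phantom import _paint_stroke

        img = np.zeros((128, 128))
        _paint_stroke(img, 64, 54, 0.0, 100.0, 1.3, 0.8)
        _paint_stroke(img, 64, 74, 0.0, 100.0, 1.3, 0.8)
        contours = detect_ridges(img * 255, PAPER_PARAMS)
        assert len(contours) == 2
        ys = sorted(c.points[:, 1].mean() for c in contours)
        assert ys[0] == pytest.approx(54, abs=0.5)
        assert ys[1] == pytest.approx(74, abs=0.5)

    def test_raising_upper_threshold_never_adds_contours(self):
        img = render_line(70.0) + render_line(160.0, amplitude=60.0)
        counts = [
            len(detect_ridges(img, RidgeParams(upper_threshold=u)))
            for u in (1.0, 3.74, 10.0, 40.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_geometry_invariant_to_intensity_scale(self):
        img = render_line(45.0)
        base = detect_ridges(img, PAPER_PARAMS)
        scaled = detect_ridges(
            img * 3.0,
            RidgeParams(lower_threshold=0.0, upper_threshold=3.74 * 3.0),
        )
        assert len(base) == len(scaled)
        np.testing.assert_allclose(base[0].points, scaled[0].points, atol=1e-6)

    def test_rotation_by_90_degrees_shifts_angles(self):
        img = render_line(20.0)
        rot = np.rot90(img)
        a = detect_ridges(img, PAPER_PARAMS)
        b = detect_ridges(rot, PAPER_PARAMS)
        assert abs(len(a) - len(b)) <= max(1, round(0.1 * len(a)))

        def chord_angle(c):
            dx, dy = c.end_point - c.start_point
            return np.degrees(np.arctan2(dy, dx)) % 180

        diff = (chord_angle(a[0]) - chord_angle(b[0])) % 180
        assert min(diff, 180 - diff) == pytest.approx(90.0, abs=1.0)

    def test_max_contour_cap_keeps_longest(self):
        img = render_line(0.0, length_px=80) + np.roll(render_line(0.0, length_px=40), 30, axis=0)
        kept = detect_ridges(img, RidgeParams(max_line_count_or_length=1))
        assert len(kept) == 1
        assert kept[0].length_px > 60


class TestRidgeCsv:
    def test_empty_contour_list_is_header_only(self):
        df = contour_to_csv([])
        assert list(df.columns) == ["contour_id", "point_index", "x", "y", "length"]
        assert df.empty

    def test_one_contour_three_rows(self):
        c = RidgeContour(5, np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]]))
        df = contour_to_csv([c])
        assert len(df) == 3
        assert set(df["contour_id"]) == {5}

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(
        st.lists(
            st.tuples(st.floats(0, 500), st.floats(0, 500)), min_size=2, max_size=8
        ),
        min_size=0, max_size=5,
    ))
    def test_round_trip_preserves_geometry(self, point_lists):
        contours = [
            RidgeContour(i, np.array(pts)) for i, pts in enumerate(point_lists)
        ]
        back = read_ridge_csv(contour_to_csv(contours))
        assert len(back) == len(contours)
        for orig, rt in zip(contours, back):
            assert rt.contour_id == orig.contour_id
            np.testing.assert_allclose(rt.points, orig.points, atol=1e-4)

    def test_imagej_style_headers_and_extras_accepted(self):
        # synthetic stand-in for the ImageJ plugin's "Results" export layout
        fixture = Path(__file__).parent / "data" / "imagej_ridges_synthetic.csv"
        with pytest.warns(UserWarning, match="extra"):
            contours = read_ridge_csv(str(fixture))
        assert [c.contour_id for c in contours] == [0, 1]
        assert len(contours[0].points) == 3
        np.testing.assert_allclose(contours[0].points[0], [12.437, 30.191])

    def test_missing_column_named_in_error(self):
        df = pd.DataFrame({"contour_id": [0], "x": [1.0], "y": [2.0]})
        with pytest.raises(ValueError, match="point_index"):
            read_ridge_csv(df)

    def test_malformed_row_reports_line_number(self):
        csv = io.StringIO(
            "contour_id,point_index,x,y,length\n0,0,1.0,2.0,5.0\n0,1,oops,3.0,5.0\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_ridge_csv(pd.read_csv(csv))
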