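"""Length-weighted axial angle statistics for ridge contours.

A contour's orientation is the axial angle of its start-to-end chord against
the image horizontal: ``atan2(dy, dx)`` folded into [0, 180), with image
coordinates as stored (origin top-left, x rightward, y downward; no axis
flip).  Angles are *axial* data — alpha and alpha+180 are the same
orientation.

Two mean estimators are provided.  The arithmetic length-weighted mean is
the literal per-section procedure (simple, but discontinuous where angles
straddle the 0/180 fold); the axial (doubled-angle vector) mean is the
circular-statistics estimator, continuous everywhere.  Both are exposed and
downstream profiles record which one was used; a warning is attached when a
section's weight concentrates near the fold, where the arithmetic mean is
unreliable.

The dispersion (polarization) statistic is the sample standard deviation of
segment angles referenced to the *vertical* axis: low SD means all segments
share one direction (high polarization), high SD means segments point every
way.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AngleMeasurement",
    "DispersionResult",
    "REGIONS",
    "contour_angle",
    "measure_contours",
    "weighted_mean_angle",
    "apply_section_correction",
    "angle_dispersion",
]

logger = logging.getLogger(__name__)

REGIONS = ("proximal", "mid", "distal", "chiasm", "tract")


@dataclass(frozen=True)
class AngleMeasurement:
    contour_id: int
    angle_deg: float  # axial, in [0, 180), vs image horizontal
    weight: float  # ridge line length in px

    def __post_init__(self):
        if not (0.0 <= self.angle_deg < 180.0):
            raise ValueError("angle_deg must lie in [0, 180)")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


@dataclass
class DispersionResult:
    channel_label: str
    region_label: str | None
    sd_deg: float
    mean_deg: float
    n_segments: int

    def __post_init__(self):
        if self.region_label is not None and self.region_label not in REGIONS:
            raise ValueError(f"region_label must be one of {REGIONS}")
        if self.sd_deg < 0:
            raise ValueError("sd_deg must be >= 0")
        if self.n_segments < 2:
            raise ValueError("dispersion needs >= 2 segments")


def contour_angle(contour) -> AngleMeasurement | None:
    """Axial chord angle and length weight of one contour.

    Returns None (with a logged warning) for closed contours whose start and
    end coincide — they carry no chord orientation.
    """
    dx, dy = np.asarray(contour.end_point, float) - np.asarray(contour.start_point, float)
    if dx == 0 and dy == 0:
        logger.warning(
            "contour %s has coincident endpoints; measurement skipped",
            getattr(contour, "contour_id", "?"),
        )
        return None
    angle = np.degrees(np.arctan2(dy, dx)) % 180.0
    return AngleMeasurement(
        contour_id=contour.contour_id, angle_deg=float(angle), weight=contour.length_px
    )


def measure_contours(contours) -> list[AngleMeasurement]:
    """contour_angle over a contour list, skipping degenerate contours."""
    out = []
    for c in contours:
        m = contour_angle(c)
        if m is not None:
            out.append(m)
    return out


def _angles_weights(measurements) -> tuple[np.ndarray, np.ndarray]:
    if len(measurements) == 0:
        raise ValueError("no angle measurements")
    a = np.array([m.angle_deg for m in measurements], dtype=float)
    w = np.array([m.weight for m in measurements], dtype=float)
    return a, w


def weighted_mean_angle(measurements, mode: str = "arithmetic") -> float:
    """Length-weighted mean orientation of a section's contours.

    mode="arithmetic"
        sum(w*a)/sum(w) on angles in [0,180) — the plain weighted average.
    mode="axial"
        half the argument of sum(w * exp(2i*a)), folded to [0,180) — the
        axial circular mean, continuous across the fold.  Raises when the
        resultant vanishes (no defined mean orientation).

    A warning is emitted in arithmetic mode when more than 10% of the total
    weight lies within 10 degrees of the 0/180 fold, where the arithmetic
    average of axial data is unreliable.
    """
    a, w = _angles_weights(measurements)
    if mode == "arithmetic":
        near_fold = (a < 10.0) | (a > 170.0)
        if w[near_fold].sum() > 0.10 * w.sum():
            warnings.warn(
                ">10% of contour weight lies within 10 deg of the 0/180 fold; "
                "the arithmetic axial mean may be unreliable here",
                stacklevel=2,
            )
        return float(np.sum(w * a) / np.sum(w))
    if mode == "axial":
        two = np.deg2rad(2.0 * a)
        cx = np.sum(w * np.cos(two))
        sx = np.sum(w * np.sin(two))
        if np.hypot(cx, sx) < 1e-9 * w.sum():
            raise ValueError("undefined mean: axial resultant length is ~0")
        return float((np.degrees(np.arctan2(sx, cx)) / 2.0) % 180.0)
    raise ValueError(f"unknown mode {mode!r}; use 'arithmetic' or 'axial'")


def apply_section_correction(mean_angle: float, placement_angle: float) -> float:
    """Remove the slide-placement angle of a section from its mean angle.

    Hand placement of paraffin sections rotates each section by the angle its
    edge makes with the slide edge; subtracting it (mod 180) restores a
    common reference frame across sections.
    """
    if not (np.isfinite(mean_angle) and np.isfinite(placement_angle)):
        raise ValueError("angles must be finite")
    return float((mean_angle - placement_angle) % 180.0)


def vertical_reference(angles_deg: np.ndarray) -> np.ndarray:
    """Signed deviation from the vertical axis, in [-90, 90)."""
    return ((90.0 - np.asarray(angles_deg, float)) + 90.0) % 180.0 - 90.0


def angle_dispersion(
    measurements,
    weighting: str = "none",
    channel_label: str = "",
    region_label: str | None = None,
) -> DispersionResult:
    """Polarization statistic: SD of segment angles referenced to vertical.

    Sample standard deviation (n-1 denominator), unweighted by default
    (``weighting="length"`` uses the length weights).  Angles are re-expressed
    as signed deviations from vertical before averaging, so fields whose
    segments cluster around the vertical/longitudinal axis sit far from the
    axial fold.
    """
    a, w = _angles_weights(measurements)
    if len(a) < 2:
        raise ValueError("dispersion needs >= 2 measurements")
    v = vertical_reference(a)
    if weighting == "none":
        sd = float(np.std(v, ddof=1))
        mean = float(np.mean(v))
    elif weighting == "length":
        mean = float(np.sum(w * v) / np.sum(w))
        var = np.sum(w * (v - mean) ** 2) / (np.sum(w) * (len(v) - 1) / len(v))
        sd = float(np.sqrt(var))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return DispersionResult(
        channel_label=channel_label,
        region_label=region_label,
        sd_deg=sd,
        mean_deg=mean,
        n_segments=len(a),
    )
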