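"""Synthetic serial-section fiber phantoms with known orientation ground truth.

A coronal section through a white-matter tract shows two kinds of Gfap+
profile: fibers running *along* the nerve are cut across and appear as small
round blobs ("longitudinal" class), while fibers lying in the section plane
appear as elongated strokes ("transverse/vertical" class).  The generator
paints both on a dark background so every downstream stage — ridge
detection, angle statistics, Bernsen particle classification and the
polynomial orientation profile — can be validated against exact truth.

Conventions
-----------
Images are indexed ``[row, col]``; a point is ``(x, y) = (col, row)`` with
origin at the top-left corner.  In-plane orientations are *axial* angles in
degrees in ``[0, 180)`` measured from the +x axis as ``atan2(dy, dx)`` folded
modulo 180 (no y-axis flip).  Axial angles are sampled by drawing a circular
von Mises variate on the doubled angle and halving — the standard axial-data
construction.

All shapes have Gaussian intensity profiles; the "footprint" of a shape is
its half-maximum iso-contour, so painted areas have closed forms: a stroke of
length ``L`` and cross-section ``sigma_w`` covers a capsule of radius
``r = sigma_w*sqrt(2 ln 2)`` (area ``2 L r + pi r^2``) and a blob drawn for
target area ``A`` covers exactly ``A``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "SectionTruth",
    "ChannelPair",
    "generate_section",
    "generate_series",
    "generate_channel_pair",
    "sample_axial_von_mises",
    "find_inflections_numeric",
]

_HALF_MAX = np.sqrt(2.0 * np.log(2.0))  # half-max radius of a unit-sigma Gaussian


def sample_axial_von_mises(
    mean_deg: float, kappa: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw axial angles (degrees in [0,180)) around ``mean_deg``.

    The doubled angle ``2*alpha`` is von Mises distributed with mean
    ``2*mean_deg`` and concentration ``kappa``; ``kappa=0`` gives the uniform
    axial distribution and ``kappa -> inf`` collapses onto the mean.
    """
    phi = rng.vonmises(np.deg2rad(2.0 * mean_deg), kappa, size=size)
    return (np.rad2deg(phi) / 2.0) % 180.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a serial-section phantom study.

    Parameters
    ----------
    theta_fn : callable
        Mean axial stroke angle (degrees in [0,180)) as a function of
        normalized nerve position ``z`` in [0,1].
    kappa : float
        von Mises concentration of the axial angle distribution (applied on
        doubled angles).  ``kappa=8`` gives an axial spread of roughly 14deg.
    longitudinal_fraction_fn : callable
        Fraction of fibers per section drawn as round longitudinal
        cross-sections, as a function of ``z``.
    blob_area_um2_range : (lo, hi)
        Uniform range of blob areas; ``hi`` must not exceed 25 so the
        generator's class labels agree with the area-based classifier cutoff.
    transitions : sequence of float
        Tissue-environment transition positions in (0,1), strictly
        increasing.  Recorded in the truth for transition-matching tests.
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    n_sections: int = 60
    theta_fn: Callable[[float], float] = lambda z: 90.0
    kappa: float = 8.0
    longitudinal_fraction_fn: Callable[[float], float] = lambda z: 0.3
    n_fibers_per_section: int = 60
    fiber_width_um: float = 1.0
    fiber_length_um_lognormal: tuple[float, float] = (np.log(18.0), 0.35)
    blob_area_um2_range: tuple[float, float] = (5.0, 15.0)
    noise_gaussian_sd: float = 0.01
    noise_poisson: bool = False
    # per-section jitter of the mean stroke angle (degrees): residual
    # placement error that survives the slide-angle correction
    section_angle_noise_sd_deg: float = 0.0
    transitions: tuple[float, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.blob_area_um2_range[1] > 25.0:
            raise ValueError(
                "blob_area_um2_range upper bound must be <= 25 um^2 so generator "
                "class labels agree with the area classifier"
            )
        if self.blob_area_um2_range[0] <= 0:
            raise ValueError("blob areas must be positive")
        if self.noise_gaussian_sd < 0:
            raise ValueError("noise_gaussian_sd must be >= 0")
        tr = list(self.transitions)
        if any(not (0.0 < t < 1.0) for t in tr):
            raise ValueError("transitions must lie strictly inside (0,1)")
        if any(b <= a for a, b in zip(tr, tr[1:])):
            raise ValueError("transitions must be strictly increasing")
        if self.n_fibers_per_section < 1:
            raise ValueError("n_fibers_per_section must be >= 1")


@dataclass
class SectionTruth:
    """Exact ground truth for one generated section."""

    z: float
    mean_angle_deg: float
    fiber_angles_deg: list[float]
    n_longitudinal: int
    n_transverse: int
    longitudinal_area_um2: float
    transverse_area_um2: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PhantomTruth:
    per_section: list[SectionTruth]
    inflection_points_true: list[float]
    transitions: list[float]

    def to_json(self, path) -> None:
        payload = {
            "schema_version": 1,
            "per_section": [s.to_dict() for s in self.per_section],
            "inflection_points_true": self.inflection_points_true,
            "transitions": self.transitions,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PhantomTruth":
        with open(path) as fh:
            payload = json.load(fh)
        sections = [SectionTruth(**s) for s in payload["per_section"]]
        return cls(sections, payload["inflection_points_true"], payload["transitions"])


@dataclass
class ChannelPair:
    """Two co-registered single-channel phantoms sharing a mean orientation.

    ``channel_a`` plays the astrocyte-reporter channel and ``channel_b`` the
    axon-marker channel; their angular concentrations are coupled by the
    generator's monotone coupling rule so downstream dispersion statistics of
    the two channels are correlated by construction.
    """

    channel_a: np.ndarray
    channel_b: np.ndarray
    kappa_a: float
    kappa_b: float
    shared_mean_angle_deg: float
    angles_a: list[float] = field(default_factory=list)
    angles_b: list[float] = field(default_factory=list)


# ----------------------------------------------------------------------
# rendering primitives


def _paint_stroke(img, cx, cy, angle_deg, length_px, sigma_px, amp) -> None:
    """Additively paint a Gaussian-profile capsule stroke (in place)."""
    h, w = img.shape
    ux = np.cos(np.deg2rad(angle_deg))
    uy = np.sin(np.deg2rad(angle_deg))
    half = length_px / 2.0
    pad = 4.0 * sigma_px
    x0 = max(int(np.floor(cx - half - pad)), 0)
    x1 = min(int(np.ceil(cx + half + pad)) + 1, w)
    y0 = max(int(np.floor(cy - half - pad)), 0)
    y1 = min(int(np.ceil(cy + half + pad)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    gx, gy = np.meshgrid(xs, ys)
    # distance to the centre segment: project onto the axis, clamp to ends
    t = np.clip(gx * ux + gy * uy, -half, half)
    d2 = (gx - t * ux) ** 2 + (gy - t * uy) ** 2
    img[y0:y1, x0:x1] += amp * np.exp(-d2 / (2.0 * sigma_px**2))


def _paint_blob(img, cx, cy, area_um2, pixel_size_um, amp) -> None:
    """Additively paint an isotropic Gaussian blob whose half-max disc has
    exactly ``area_um2`` (in place)."""
    area_px = area_um2 / pixel_size_um**2
    sigma_px = np.sqrt(area_px / (2.0 * np.pi * np.log(2.0)))
    h, w = img.shape
    pad = 4.0 * sigma_px
    x0 = max(int(np.floor(cx - pad)), 0)
    x1 = min(int(np.ceil(cx + pad)) + 1, w)
    y0 = max(int(np.floor(cy - pad)), 0)
    y1 = min(int(np.ceil(cy + pad)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    gx, gy = np.meshgrid(xs, ys)
    d2 = gx**2 + gy**2
    img[y0:y1, x0:x1] += amp * np.exp(-d2 / (2.0 * sigma_px**2))


def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 2-D segments."""
    p0, p1, q0, q1 = (np.asarray(v, float) for v in (p0, p1, q0, q1))
    d1 = p1 - p0
    d2 = q1 - q0
    r = p0 - q0
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    if a <= 1e-12 and e <= 1e-12:
        return float(np.hypot(*r))
    if a <= 1e-12:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= 1e-12:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    diff = (p0 + s * d1) - (q0 + t * d2)
    return float(np.hypot(*diff))


def _stroke_area_um2(length_um: float, sigma_um: float) -> float:
    """Half-maximum footprint area of a capsule stroke, in um^2."""
    r = _HALF_MAX * sigma_um
    return 2.0 * length_um * r + np.pi * r**2


def _apply_noise(img, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_poisson:
        # shot noise at a photon budget of 1000 counts per unit intensity
        img = rng.poisson(np.clip(img, 0, None) * 1000.0) / 1000.0
    if spec.noise_gaussian_sd > 0:
        img = img + rng.normal(0.0, spec.noise_gaussian_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


# ----------------------------------------------------------------------
# public generators


def generate_section(
    spec: PhantomSpec, z: float, rng: np.random.Generator
) -> tuple[np.ndarray, SectionTruth]:
    """Render one coronal section at normalized position ``z``.

    Returns a float image in [0,1] and the exact per-section truth.  The
    transverse stroke count is ``round(n_fibers * (1 - longitudinal_fraction))``
    and the remainder is drawn as longitudinal blobs; every stroke angle and
    every painted half-max area is recorded.
    """
    spec.validate()
    if not (0.0 <= z <= 1.0):
        raise ValueError(f"z must lie in [0,1], got {z}")
    h, w = spec.image_size_px
    img = np.zeros((h, w), dtype=np.float64)

    frac_long = float(np.clip(spec.longitudinal_fraction_fn(z), 0.0, 1.0))
    n_trans = int(round(spec.n_fibers_per_section * (1.0 - frac_long)))
    n_long = spec.n_fibers_per_section - n_trans

    mean_angle = float(spec.theta_fn(z)) % 180.0
    if spec.section_angle_noise_sd_deg > 0:
        mean_angle = (mean_angle + rng.normal(0.0, spec.section_angle_noise_sd_deg)) % 180.0
    sigma_px = spec.fiber_width_um / spec.pixel_size_um
    amp = 0.8

    angles = sample_axial_von_mises(mean_angle, spec.kappa, n_trans, rng)
    trans_area = 0.0
    for ang in angles:
        mu, sg = spec.fiber_length_um_lognormal
        length_um = float(rng.lognormal(mu, sg))
        length_px = length_um / spec.pixel_size_um
        # inset the centre so the whole stroke paints in-frame and the
        # analytic truth area matches what lands on the image
        m = min(length_px / 2.0 + 3.0 * sigma_px, (min(h, w) - 1) / 2.0)
        cx = rng.uniform(m, w - 1 - m)
        cy = rng.uniform(m, h - 1 - m)
        _paint_stroke(img, cx, cy, float(ang), length_px, sigma_px, amp)
        trans_area += _stroke_area_um2(length_um, spec.fiber_width_um)

    long_area = 0.0
    lo, hi = spec.blob_area_um2_range
    for _ in range(n_long):
        area = float(rng.uniform(lo, hi))
        sigma_b = np.sqrt(area / spec.pixel_size_um**2 / (2.0 * np.pi * np.log(2.0)))
        m = min(4.0 * sigma_b, (min(h, w) - 1) / 2.0)
        cx = rng.uniform(m, w - 1 - m)
        cy = rng.uniform(m, h - 1 - m)
        _paint_blob(img, cx, cy, area, spec.pixel_size_um, amp)
        long_area += area

    img = _apply_noise(img, spec, rng)
    truth = SectionTruth(
        z=float(z),
        mean_angle_deg=mean_angle,
        fiber_angles_deg=[float(a) for a in angles],
        n_longitudinal=n_long,
        n_transverse=n_trans,
        longitudinal_area_um2=long_area,
        transverse_area_um2=trans_area,
    )
    return img, truth


def find_inflections_numeric(
    theta_fn: Callable[[float], float],
    dz: float = 1e-4,
    boundary_margin: float = 1e-3,
    rel_tol: float = 1e-8,
) -> list[float]:
    """Interior inflection points of ``theta_fn`` by dense finite differences.

    The second derivative is evaluated on a uniform grid with central
    differences; sign changes are refined by linear interpolation.  Roots at
    (or numerically indistinguishable from) the domain boundary are excluded,
    as is the degenerate case of an (almost) everywhere-zero second
    derivative, which has no isolated roots.
    """
    zs = np.arange(0.0, 1.0 + dz / 2, dz)
    f = np.array([theta_fn(float(z)) for z in zs], dtype=np.float64)
    d2 = np.empty_like(f)
    d2[1:-1] = (f[2:] - 2 * f[1:-1] + f[:-2]) / dz**2
    d2[0], d2[-1] = d2[1], d2[-2]
    scale = np.max(np.abs(d2))
    # central differences amplify float rounding of f by ~1/dz^2; curvature
    # below that noise bound is indistinguishable from an identically-zero
    # second derivative (no isolated roots)
    noise_floor = 1e3 * np.finfo(float).eps * max(1.0, np.max(np.abs(f))) / dz**2
    if scale <= noise_floor:
        return []
    # sign changes between consecutive *non-negligible* entries: a grid point
    # can land exactly on a root and read 0.0, which must not mask the flip
    keep = np.nonzero(np.abs(d2) > max(noise_floor, rel_tol * scale))[0]
    roots: list[float] = []
    for i, j in zip(keep[:-1], keep[1:]):
        if d2[i] * d2[j] >= 0:
            continue
        root = zs[i] + (zs[j] - zs[i]) * d2[i] / (d2[i] - d2[j])
        if boundary_margin < root < 1.0 - boundary_margin:
            roots.append(float(root))
    return roots


def generate_series(spec: PhantomSpec) -> tuple[list[np.ndarray], PhantomTruth]:
    """Render the full serial-section series at z = i/(n_sections-1).

    Fewer than 8 sections is refused: the downstream degree-7 orientation
    fit would be ill-posed.
    """
    spec.validate()
    if spec.n_sections < 8:
        raise ValueError("n_sections must be >= 8 to support a degree-7 fit")
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_sections)
    images: list[np.ndarray] = []
    sections: list[SectionTruth] = []
    for i, ss in enumerate(children):
        z = i / (spec.n_sections - 1)
        img, truth = generate_section(spec, z, np.random.default_rng(ss))
        images.append(img)
        sections.append(truth)
    inflections = find_inflections_numeric(spec.theta_fn)
    return images, PhantomTruth(sections, inflections, list(spec.transitions))


def _check_monotone(coupling: Callable[[float], float]) -> None:
    grid = np.logspace(-2, 3, 40)
    vals = np.array([coupling(float(k)) for k in grid])
    if np.any(np.diff(vals) < 0):
        raise ValueError("coupling must be a monotone (non-decreasing) map")


def generate_channel_pair(
    mean_angle: float,
    kappa_b: float,
    coupling: Callable[[float], float],
    n_segments: int,
    seed: int,
    image_size_px: tuple[int, int] = (384, 384),
    pixel_size_um: float = 0.35,
    fiber_width_um: float = 0.6,
    fiber_length_um_lognormal: tuple[float, float] = (np.log(12.0), 0.3),
    noise_gaussian_sd: float = 0.01,
    min_separation_px: float = 8.0,
) -> ChannelPair:
    """Paired two-channel phantom with coupled angular dispersion.

    Both channels draw their stroke angles around the same axial mean;
    channel B uses ``kappa_b`` and channel A uses ``coupling(kappa_b)``.
    The truth (kappas and drawn angles) supports regression of the two
    channels' downstream dispersion statistics on one another.
    """
    if kappa_b <= 0:
        raise ValueError("kappa_b must be > 0")
    if n_segments < 10:
        raise ValueError("n_segments must be >= 10")
    _check_monotone(coupling)
    kappa_a = float(coupling(kappa_b))
    rng = np.random.default_rng(seed)
    h, w = image_size_px
    sigma_px = fiber_width_um / pixel_size_um
    mu, sg = fiber_length_um_lognormal

    def _render(kappa: float) -> tuple[np.ndarray, list[float]]:
        img = np.zeros((h, w), dtype=np.float64)
        angles = sample_axial_von_mises(mean_angle, kappa, n_segments, rng)
        # dart-throwing placement: keep whole strokes apart so side-by-side
        # parallel strokes do not fuse into one detected contour
        placed: list[tuple[np.ndarray, np.ndarray]] = []
        for ang in angles:
            length_px = rng.lognormal(mu, sg) / pixel_size_um
            m = min(length_px / 2.0 + 3.0 * sigma_px, (min(h, w) - 1) / 2.0)
            u = np.array([np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))])
            for _ in range(300):
                c = np.array([rng.uniform(m, w - 1 - m), rng.uniform(m, h - 1 - m)])
                p0, p1 = c - 0.5 * length_px * u, c + 0.5 * length_px * u
                if all(
                    _segment_distance(p0, p1, q0, q1) >= min_separation_px
                    for q0, q1 in placed
                ):
                    break
            placed.append((p0, p1))
            _paint_stroke(img, c[0], c[1], float(ang), length_px, sigma_px, 0.8)
        if noise_gaussian_sd > 0:
            img = img + rng.normal(0.0, noise_gaussian_sd, img.shape)
        return np.clip(img, 0.0, 1.0), [float(a) for a in angles]

    channel_a, angles_a = _render(kappa_a)
    channel_b, angles_b = _render(kappa_b)
    return ChannelPair(
        channel_a=channel_a,
        channel_b=channel_b,
        kappa_a=kappa_a,
        kappa_b=kappa_b,
        shared_mean_angle_deg=float(mean_angle) % 180.0,
        angles_a=angles_a,
        angles_b=angles_b,
    )
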