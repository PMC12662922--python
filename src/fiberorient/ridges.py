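"""Subpixel detection of curvilinear structures (Steger's method).

Bright lines on a dark background are modelled as ridges of the image
intensity surface.  At scale ``sigma`` the image is convolved with Gaussian
derivative kernels; at each pixel the eigenvector of the Hessian belonging
to the most negative eigenvalue gives the direction ``n`` perpendicular to a
putative line, and a second-order Taylor expansion locates the point where
the first directional derivative along ``n`` vanishes.  Pixels whose
vanishing point falls inside the pixel are line points; the magnitude of the
second directional derivative is the line strength used for hysteresis
thresholding, and accepted points are linked into ordered subpixel contours.

Only the bright-line mode is implemented: fluorescence labeling is signal on
a dark background.  Line width estimation and junction resolution are out of
scope — downstream analysis uses only start/end positions and lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = ["RidgeParams", "RidgeContour", "detect_ridges", "contour_to_csv", "read_ridge_csv"]

# step offsets by tangent octant: for each of 8 coarse directions, the three
# 8-neighbour moves (dx, dy) within +/-45 degrees of that direction
_OCT_STEPS = {}
for _k in range(8):
    _ang = _k * 45.0
    _steps = []
    for _dx, _dy in ((1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)):
        _sa = np.rad2deg(np.arctan2(_dy, _dx)) % 360.0
        _diff = abs((_sa - _ang + 180.0) % 360.0 - 180.0)
        if _diff <= 45.0 + 1e-9:
            _steps.append((_dx, _dy))
    _OCT_STEPS[_k] = tuple(_steps)


@dataclass(frozen=True)
class RidgeParams:
    """Detector parameterization.

    ``sigma`` is the Gaussian derivative scale in pixels; when absent it is
    derived from the expected ``line_width`` as ``w/(2*sqrt(3)) + 0.5`` (the
    usual rule for bar-shaped lines).  ``lower_threshold``/``upper_threshold``
    bound the hysteresis on line strength (the absolute second directional
    derivative).  ``high_contrast``/``low_contrast`` mirror the ImageJ
    plugin's threshold-estimation convention; they are stored for provenance
    but the explicit thresholds govern.  ``max_line_count_or_length`` caps the
    number of retained contours, longest first.
    """

    sigma: float = 1.2
    lower_threshold: float = 0.0
    upper_threshold: float = 3.74
    min_line_length: float = 2.0
    max_line_count_or_length: int = 200
    line_width: float = 6.0
    high_contrast: float = 255.0
    low_contrast: float = 10.0

    def __post_init__(self):
        sigma = self.sigma
        if sigma is None:
            sigma = self.line_width / (2.0 * np.sqrt(3.0)) + 0.5
            object.__setattr__(self, "sigma", sigma)
        if sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.lower_threshold < 0:
            raise ValueError("lower_threshold must be >= 0")
        if self.upper_threshold < self.lower_threshold:
            raise ValueError("upper_threshold must be >= lower_threshold")
        if self.min_line_length < 0:
            raise ValueError("min_line_length must be >= 0")


@dataclass
class RidgeContour:
    """An ordered subpixel polyline: the unit of orientation measurement."""

    contour_id: int
    points: np.ndarray  # (n, 2) array of subpixel (x, y)
    strengths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("a contour needs >= 2 (x, y) points")
        if self.strengths is None:
            self.strengths = np.zeros(len(self.points))
        else:
            self.strengths = np.asarray(self.strengths, dtype=np.float64)

    @property
    def length_px(self) -> float:
        """Polyline arc length in pixels."""
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    @property
    def start_point(self) -> np.ndarray:
        return self.points[0]

    @property
    def end_point(self) -> np.ndarray:
        return self.points[-1]


def _hessian_line_points(image: np.ndarray, sigma: float):
    """Per-pixel line-point geometry from Gaussian derivatives.

    Returns (valid, strength, px, py, nx, ny): boolean mask of subpixel line
    points (bright-line condition, vanishing directional derivative within
    the pixel), the line strength |d2/dn2|, the subpixel coordinates and the
    unit normal per pixel.
    """
    img = image.astype(np.float64, copy=False)
    # axis 0 = y (rows), axis 1 = x (cols)
    rx = ndi.gaussian_filter(img, sigma, order=(0, 1), mode="nearest")
    ry = ndi.gaussian_filter(img, sigma, order=(1, 0), mode="nearest")
    rxx = ndi.gaussian_filter(img, sigma, order=(0, 2), mode="nearest")
    rxy = ndi.gaussian_filter(img, sigma, order=(1, 1), mode="nearest")
    ryy = ndi.gaussian_filter(img, sigma, order=(2, 0), mode="nearest")

    # eigenvalues of [[rxx, rxy], [rxy, ryy]]; the most negative one
    # belongs to the direction across a bright line
    disc = np.sqrt((rxx - ryy) ** 2 + 4.0 * rxy**2)
    lam = 0.5 * (rxx + ryy - disc)
    lam2 = 0.5 * (rxx + ryy + disc)
    # eigenvector for lam: (rxy, lam - rxx), degenerate when rxy ~ 0
    nx = np.where(np.abs(rxy) > 1e-12, rxy, np.where(rxx <= ryy, 1.0, 0.0))
    ny = np.where(np.abs(rxy) > 1e-12, lam - rxx, np.where(rxx <= ryy, 0.0, 1.0))
    norm = np.hypot(nx, ny)
    norm[norm == 0] = 1.0
    nx /= norm
    ny /= norm

    d2 = rxx * nx**2 + 2.0 * rxy * nx * ny + ryy * ny**2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -(rx * nx + ry * ny) / d2
    t = np.where(np.isfinite(t), t, np.inf)
    with np.errstate(invalid="ignore"):
        tx = np.where(np.isfinite(t), t * nx, np.inf)
        ty = np.where(np.isfinite(t), t * ny, np.inf)

    strength = np.abs(lam)
    # a floor relative to the peak response rejects flat background where the
    # eigenvalue is only numerical noise (matters when lower_threshold == 0)
    noise_floor = 1e-4 * strength.max() if strength.size else 0.0
    # 1-D structure condition: the along-line eigenvalue must be small in
    # magnitude compared with the cross-line one; this excludes dome-shaped
    # blob responses (both curvatures negative, e.g. at line end-caps) and
    # the decaying axial tail just past an end-cap (strongly convex along
    # the line axis)
    valid = (
        (lam < -noise_floor)
        & (np.abs(lam2) <= 0.25 * np.abs(lam))
        & (np.abs(tx) <= 0.5 + 1e-9)
        & (np.abs(ty) <= 0.5 + 1e-9)
    )

    h, w = img.shape
    gx, gy = np.meshgrid(np.arange(w), np.arange(h))
    px = gx + np.where(valid, tx, 0.0)
    py = gy + np.where(valid, ty, 0.0)
    return valid, strength, px, py, nx, ny


def _axial_diff_deg(a: float, b: float) -> float:
    """Smallest difference between two orientations defined modulo 180."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def detect_ridges(image: np.ndarray, params: RidgeParams) -> list[RidgeContour]:
    """Extract subpixel ridge contours from a 2-D grayscale image.

    Line points with strength >= ``upper_threshold`` seed contours (strongest
    first); linking extends each seed along the local tangent through
    neighbouring line points with strength >= ``lower_threshold`` whose
    orientation differs by at most 45 degrees per step.  Contours shorter
    than ``min_line_length`` are dropped and at most
    ``max_line_count_or_length`` contours are kept, longest first.  Pixels
    within ``ceil(3*sigma)`` of the border do not seed contours (derivative
    filters are unreliable there), though contours may extend into them.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    valid, strength, px, py, nx, ny = _hessian_line_points(image, params.sigma)
    h, w = image.shape

    linkable = valid & (strength >= params.lower_threshold) & (strength > 0)
    border = int(np.ceil(3.0 * params.sigma))
    seedable = linkable & (strength >= params.upper_threshold)
    if border > 0:
        interior = np.zeros_like(seedable)
        if h > 2 * border and w > 2 * border:
            interior[border:-border, border:-border] = True
        seedable &= interior

    # orientation of the local tangent (perpendicular to the normal), axial
    tang_deg = np.rad2deg(np.arctan2(nx, -ny)) % 180.0

    seeds = np.argwhere(seedable)
    if len(seeds) == 0:
        return []
    order = np.argsort(strength[seeds[:, 0], seeds[:, 1]])[::-1]
    seeds = seeds[order]

    used = np.zeros_like(linkable)
    raw: list[tuple[list[tuple[int, int]], None]] = []

    def _walk(r0: int, c0: int, direction: int) -> list[tuple[int, int]]:
        """Follow the line from (r0, c0) along tangent or anti-tangent."""
        path: list[tuple[int, int]] = []
        r, c = r0, c0
        ang = tang_deg[r, c]
        # initial step direction in degrees (full circle)
        head = ang if direction == 0 else (ang + 180.0) % 360.0
        while True:
            octant = int(round(head / 45.0)) % 8
            best = None
            for dx, dy in _OCT_STEPS[octant]:
                rr, cc = r + dy, c + dx
                if not (0 <= rr < h and 0 <= cc < w):
                    continue
                if used[rr, cc] or not linkable[rr, cc]:
                    continue
                dang = _axial_diff_deg(tang_deg[rr, cc], tang_deg[r, c])
                if dang > 45.0:
                    continue
                dist = np.hypot(px[rr, cc] - px[r, c], py[rr, cc] - py[r, c])
                score = dist + np.deg2rad(dang)
                if best is None or score < best[0]:
                    best = (score, rr, cc, dx, dy)
            if best is None:
                return path
            _, rr, cc, dx, dy = best
            used[rr, cc] = True
            path.append((rr, cc))
            # keep heading consistent: pick the tangent orientation closest
            # to the direction of actual travel
            step_ang = np.rad2deg(np.arctan2(dy, dx)) % 360.0
            cand = tang_deg[rr, cc]
            if _full_diff(cand, step_ang) <= _full_diff(cand + 180.0, step_ang):
                head = cand % 360.0
            else:
                head = (cand + 180.0) % 360.0
            r, c = rr, cc

    def _full_diff(a: float, b: float) -> float:
        return abs((a - b + 180.0) % 360.0 - 180.0)

    for r0, c0 in seeds:
        if used[r0, c0]:
            continue
        used[r0, c0] = True
        fwd = _walk(r0, c0, 0)
        bwd = _walk(r0, c0, 1)
        pix = bwd[::-1] + [(r0, c0)] + fwd
        if len(pix) >= 2:
            raw.append((pix, None))

    contours: list[RidgeContour] = []
    for pix, _ in raw:
        rows = np.array([p[0] for p in pix])
        cols = np.array([p[1] for p in pix])
        pts = np.column_stack([px[rows, cols], py[rows, cols]])
        c = RidgeContour(contour_id=-1, points=pts, strengths=strength[rows, cols])
        if c.length_px >= params.min_line_length:
            contours.append(c)

    contours.sort(key=lambda c: c.length_px, reverse=True)
    contours = contours[: params.max_line_count_or_length]
    for i, c in enumerate(contours):
        c.contour_id = i
    return contours


# ----------------------------------------------------------------------
# CSV round-trip (column-compatible with the ImageJ plugin's Results export)

_REQUIRED = ["contour_id", "point_index", "x", "y", "length"]

# header aliases accepted when reading ImageJ "Results" exports
_ALIASES = {
    "contour id": "contour_id",
    "pos.": "point_index",
    "pos": "point_index",
    "x": "x",
    "y": "y",
    "length": "length",
}


def contour_to_csv(contours: list[RidgeContour]) -> pd.DataFrame:
    """Serialize contours to a long-format table, one row per point."""
    rows = []
    for c in contours:
        length = c.length_px
        for i, (x, y) in enumerate(c.points):
            rows.append((c.contour_id, i, x, y, length))
    return pd.DataFrame(rows, columns=_REQUIRED)


def read_ridge_csv(table: pd.DataFrame | str) -> list[RidgeContour]:
    """Rebuild contours from a table (ours or an ImageJ plugin export).

    Unknown columns are ignored with a warning; missing required columns
    raise a parse error naming the first absent column.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    renames = {}
    for col in table.columns:
        key = str(col).strip().lower()
        if key in _ALIASES:
            renames[col] = _ALIASES[key]
    df = table.rename(columns=renames)
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"ridge CSV is missing required column '{col}'")
    extras = [c for c in df.columns if c not in _REQUIRED]
    if extras:
        warnings.warn(f"ignoring extra ridge CSV columns: {extras}")
    for col in _REQUIRED:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
            raise ValueError(f"malformed value in column '{col}' at CSV line {line}")
    contours = []
    for cid, grp in df.groupby("contour_id", sort=True):
        grp = grp.sort_values("point_index")
        pts = grp[["x", "y"]].to_numpy(dtype=np.float64)
        if len(pts) < 2:
            warnings.warn(f"contour {cid} has fewer than 2 points; skipped")
            continue
        contours.append(RidgeContour(contour_id=int(cid), points=pts))
    return contours
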