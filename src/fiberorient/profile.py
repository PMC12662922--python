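"""Along-nerve orientation profile: degree-7 fit, inflections, transitions.

Per-section mean angles are assembled on a normalized nerve axis (z = 0 at
the scleral end, z = 1 at the chiasm-tract transition, uniform section
spacing), fit with a degree-7 polynomial by ordinary least squares, and the
fit's critical points (roots of p') and interior inflection points (roots of
p'' away from the domain edges) are extracted.  Inflection positions are
then scored against a map of positions where the tissue surrounding the
nerve changes: each inflection is paired with its nearest transition and the
mean absolute offset, as a fraction of nerve length, measures how closely
orientation trend changes track the tissue environment.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SectionRecord",
    "NerveProfile",
    "EnvironmentMap",
    "TransitionMatch",
    "build_profile",
    "fit_polynomial",
    "find_critical_and_inflection",
    "match_transitions",
    "average_inflections_by_rank",
]

POLY_DEGREE = 7
DEFAULT_EDGE_MARGIN = 0.05


@dataclass
class SectionRecord:
    section_index: int
    z: float
    corrected_mean_angle_deg: float
    area_ratio: float = float("nan")
    placement_angle_deg: float = 0.0


@dataclass
class NerveProfile:
    records: list[SectionRecord]
    edge_margin: float = DEFAULT_EDGE_MARGIN
    poly_coeffs: np.ndarray | None = None  # ascending powers, length 8
    residuals: np.ndarray | None = None
    critical_points: list[float] = field(default_factory=list)
    inflection_points: list[float] = field(default_factory=list)
    angle_mode: str = "arithmetic"

    def polynomial(self) -> np.polynomial.Polynomial:
        if self.poly_coeffs is None:
            raise ValueError("profile has no fitted polynomial yet")
        return np.polynomial.Polynomial(self.poly_coeffs)

    def to_json(self, path) -> None:
        payload = {
            "schema_version": 1,
            "edge_margin": self.edge_margin,
            "angle_mode": self.angle_mode,
            "records": [dataclasses.asdict(r) for r in self.records],
            "poly_coeffs": None if self.poly_coeffs is None else list(self.poly_coeffs),
            "critical_points": self.critical_points,
            "inflection_points": self.inflection_points,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class EnvironmentMap:
    """Positions along the normalized nerve where the surrounding tissue
    composition changes, with interval labels."""

    transitions: list[float]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        t = list(self.transitions)
        if any(not (0.0 < z < 1.0) for z in t):
            raise ValueError("transitions must lie strictly inside (0,1)")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("transitions must be strictly increasing and unique")

    @classmethod
    def from_csv(cls, path) -> "EnvironmentMap":
        df = pd.read_csv(path)
        if "z" not in df.columns:
            raise ValueError("environment map CSV needs a 'z' column")
        df = df.sort_values("z")
        labels = []
        if {"label_before", "label_after"} <= set(df.columns):
            labels = [
                f"{b}->{a}" for b, a in zip(df["label_before"], df["label_after"])
            ]
        return cls(transitions=[float(z) for z in df["z"]], labels=labels)


@dataclass
class TransitionMatch:
    per_inflection_error: list[float]  # fractions of nerve length
    mean_error: float
    sd_error: float
    pairing: list[tuple[int, int]]  # (inflection index, transition index)

    @property
    def mean_error_pct(self) -> float:
        return 100.0 * self.mean_error

    @property
    def sd_error_pct(self) -> float:
        return 100.0 * self.sd_error


def build_profile(
    section_summaries,
    nerve_length_sections: int | None = None,
    edge_margin: float = DEFAULT_EDGE_MARGIN,
    angle_mode: str = "arithmetic",
) -> NerveProfile:
    """Order per-section summaries onto the normalized nerve axis.

    ``section_summaries`` is a sequence of dicts (or SectionRecords) with at
    least ``section_index`` and ``corrected_mean_angle_deg``; entries whose
    angle is missing/NaN are dropped with a warning, but z for the remaining
    sections is still computed from the full nerve length
    (``nerve_length_sections``, default: max index + 1).
    """
    entries = []
    for s in section_summaries:
        if dataclasses.is_dataclass(s):
            s = dataclasses.asdict(s)
        entries.append(dict(s))
    if nerve_length_sections is None:
        nerve_length_sections = max(e["section_index"] for e in entries) + 1
    if nerve_length_sections < 8:
        raise ValueError("need >= 8 sections for a degree-7 fit")
    records = []
    for e in sorted(entries, key=lambda e: e["section_index"]):
        ang = e.get("corrected_mean_angle_deg")
        if ang is None or not np.isfinite(ang):
            warnings.warn(
                f"section {e['section_index']} has no usable angle; dropped",
                stacklevel=2,
            )
            continue
        records.append(
            SectionRecord(
                section_index=int(e["section_index"]),
                z=e["section_index"] / (nerve_length_sections - 1),
                corrected_mean_angle_deg=float(ang),
                area_ratio=float(e.get("area_ratio", float("nan"))),
                placement_angle_deg=float(e.get("placement_angle_deg", 0.0)),
            )
        )
    if len(records) < 8:
        raise ValueError(f"only {len(records)} usable sections; need >= 8")
    return NerveProfile(records=records, edge_margin=edge_margin, angle_mode=angle_mode)


def fit_polynomial(profile: NerveProfile) -> NerveProfile:
    """Ordinary least squares degree-7 fit of angle against z (in place).

    z in [0,1] is already well-conditioned for a raw Vandermonde basis.
    Rank deficiency (fewer than 8 distinct z values) raises with condition
    diagnostics.
    """
    z = np.array([r.z for r in profile.records])
    y = np.array([r.corrected_mean_angle_deg for r in profile.records])
    if len(z) < POLY_DEGREE + 1:
        raise ValueError("need >= 8 records to fit a degree-7 polynomial")
    V = np.vander(z, POLY_DEGREE + 1, increasing=True)
    coeffs, _, rank, sv = np.linalg.lstsq(V, y, rcond=None)
    if rank < POLY_DEGREE + 1:
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        raise ValueError(
            f"rank-deficient design (rank {rank} < {POLY_DEGREE + 1}, cond {cond:.3g}); "
            "are the section positions distinct?"
        )
    profile.poly_coeffs = coeffs
    profile.residuals = y - V @ coeffs
    return profile


def _real_roots(
    poly: np.polynomial.Polynomial, lo: float, hi: float, tol=1e-6, ref_scale=None
):
    coef = np.array(poly.coef, dtype=float)
    # strip float dust: least-squares fits of flat data leave ~1e-12-scale
    # higher coefficients whose formal roots are meaningless; judge dust
    # against the undifferentiated polynomial's coefficient scale
    scale = ref_scale if ref_scale is not None else (
        np.max(np.abs(coef)) if coef.size else 0.0
    )
    if scale > 0:
        coef[np.abs(coef) < 1e-9 * scale] = 0.0
    coef = np.trim_zeros(coef, "b")
    if len(coef) < 2:
        return []  # constant (or zero) polynomial: no isolated roots
    roots = np.polynomial.Polynomial(coef).roots()
    real = np.sort(roots[np.abs(roots.imag) < 1e-8].real)
    out: list[float] = []
    for r in real:
        if lo <= r <= hi and (not out or r - out[-1] > tol):
            out.append(float(r))
    return out


def find_critical_and_inflection(profile: NerveProfile) -> NerveProfile:
    """Critical points (roots of p') in [0,1] and interior inflection points
    (roots of p'') in [edge_margin, 1 - edge_margin], via the companion-matrix
    polynomial root solver; duplicates merged at 1e-6 (in place)."""
    p = profile.polynomial()
    m = profile.edge_margin
    ref = float(np.max(np.abs(p.coef)))
    profile.critical_points = _real_roots(p.deriv(1), 0.0, 1.0, ref_scale=ref)
    profile.inflection_points = _real_roots(p.deriv(2), m, 1.0 - m, ref_scale=ref)
    return profile


def match_transitions(profile: NerveProfile, env: EnvironmentMap) -> TransitionMatch:
    """Score inflection points against tissue-environment transitions.

    Each inflection point is paired with its nearest transition (ties break
    toward the smaller z); reported errors are absolute offsets as fractions
    of nerve length.
    """
    infl = list(profile.inflection_points)
    trans = list(env.transitions)
    if not infl:
        raise ValueError("profile has no inflection points to match")
    if not trans:
        raise ValueError("environment map has no transitions")
    pairing: list[tuple[int, int]] = []
    errors: list[float] = []
    for i, x in enumerate(infl):
        d = np.abs(np.array(trans) - x)
        j = int(np.argmin(d))  # argmin takes the first (smaller z) on ties
        pairing.append((i, j))
        errors.append(float(d[j]))
    mean = float(np.mean(errors))
    sd = float(np.std(errors, ddof=1)) if len(errors) > 1 else 0.0
    return TransitionMatch(
        per_inflection_error=errors, mean_error=mean, sd_error=sd, pairing=pairing
    )


def average_inflections_by_rank(inflection_lists: list[list[float]]) -> list[float]:
    """Average inflection positions across nerves, matched by rank order.

    Nerves may report different inflection counts; ranks beyond a nerve's
    count are averaged over the nerves that have them.
    """
    if not inflection_lists:
        return []
    sorted_lists = [sorted(l) for l in inflection_lists]
    max_rank = max(len(l) for l in sorted_lists)
    out = []
    for r in range(max_rank):
        vals = [l[r] for l in sorted_lists if len(l) > r]
        out.append(float(np.mean(vals)))
    return out


def plot_profile(profile: NerveProfile, env: EnvironmentMap | None = None, path=None):
    """Angle-vs-position plot with the fitted curve and transition lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = [r.z for r in profile.records]
    y = [r.corrected_mean_angle_deg for r in profile.records]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(z, y, "o", ms=4, label="sections")
    if profile.poly_coeffs is not None:
        zz = np.linspace(0, 1, 400)
        ax.plot(zz, profile.polynomial()(zz), "-", label="degree-7 fit")
    for x in profile.inflection_points:
        ax.axvline(x, color="tab:red", ls=":", lw=1)
    if env is not None:
        for x in env.transitions:
            ax.axvline(x, color="k", ls="--", lw=1, alpha=0.5)
    ax.set_xlabel("normalized nerve position z")
    ax.set_ylabel("corrected mean angle (deg)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
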