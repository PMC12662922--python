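"""Paired-channel polarization analysis.

For co-registered astrocyte-reporter and axon-marker channels of one field,
both channels are masked to the convex hull of the reference (astrocyte)
channel, segmented with the same ridge detector, and reduced to angle
dispersion (SD of segment angles vs vertical).  Per-image pairs support a
cross-channel correlation — does astrocyte polarization track axon
polarization? — and grouping by nerve region supports a one-way ANOVA with
Tukey's post-hoc test (with D'Agostino-Pearson normality checks), the
comparison that singles out the chiasm as the region of high angular spread.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .angles import DispersionResult, angle_dispersion, measure_contours
from .preprocess import convex_hull_mask
from .ridges import RidgeParams, detect_ridges

__all__ = [
    "PairedDispersion",
    "DispersionCorrelation",
    "RegionComparison",
    "paired_dispersion",
    "correlate_dispersions",
    "compare_regions",
]

logger = logging.getLogger(__name__)


@dataclass
class PairedDispersion:
    image_id: str
    region_label: str
    astro: DispersionResult
    axon: DispersionResult


@dataclass
class DispersionCorrelation:
    r_squared_sd: float
    r_squared_mean: float
    slope_sd: float
    slope_mean: float
    n_pairs: int
    defined: bool = True


@dataclass
class RegionComparison:
    groups: dict[str, list[float]]
    anova_F: float
    anova_p: float
    pairwise: list[tuple[str, str, float]]  # Tukey-adjusted p per region pair
    normality_p_per_group: dict[str, float] = field(default_factory=dict)


def paired_dispersion(
    channel_a_image: np.ndarray,
    channel_b_image: np.ndarray,
    params: RidgeParams,
    region_label: str,
    image_id: str = "",
    mask: bool = True,
) -> PairedDispersion | None:
    """Dispersion of both channels of one field, inside one shared hull mask.

    The hull is derived from channel A (the astrocyte reporter) and restricts
    both channels' measurements: detection runs on the full images (zeroing
    outside the hull first would cut fibers at the mask boundary and seed
    step-edge artifacts there) and contours with fewer than half their
    points inside the hull are discarded.  Images yielding fewer than 2
    kept contours in either channel are excluded (returns None, with the
    reason logged).
    """
    if channel_a_image.shape != channel_b_image.shape:
        raise ValueError("channels must be co-registered (same shape)")
    hull = convex_hull_mask(channel_a_image) if mask else None
    results = {}
    for label, img in (("astro", channel_a_image), ("axon", channel_b_image)):
        contours = detect_ridges(img, params)
        if hull is not None:
            contours = [c for c in contours if _inside_fraction(c, hull.mask) >= 0.5]
        ms = measure_contours(contours)
        if len(ms) < 2:
            logger.warning(
                "image %s excluded: %d contour(s) in %s channel (need >= 2)",
                image_id, len(ms), label,
            )
            return None
        results[label] = angle_dispersion(
            ms, channel_label=label, region_label=region_label
        )
    return PairedDispersion(
        image_id=image_id, region_label=region_label,
        astro=results["astro"], axon=results["axon"],
    )


def _inside_fraction(contour, mask: np.ndarray) -> float:
    cols = np.clip(np.round(contour.points[:, 0]).astype(int), 0, mask.shape[1] - 1)
    rows = np.clip(np.round(contour.points[:, 1]).astype(int), 0, mask.shape[0] - 1)
    return float(np.mean(mask[rows, cols]))


def _ols_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.slope)


def correlate_dispersions(pairs: list[PairedDispersion]) -> DispersionCorrelation:
    """R^2 of astrocyte-on-axon regression, for the SD and the mean-angle
    pairings (simple linear regression, matching a plotted line fit)."""
    if len(pairs) < 3:
        raise ValueError("need >= 3 pairs for a correlation")
    ax_sd = np.array([p.axon.sd_deg for p in pairs])
    as_sd = np.array([p.astro.sd_deg for p in pairs])
    ax_mean = np.array([p.axon.mean_deg for p in pairs])
    as_mean = np.array([p.astro.mean_deg for p in pairs])
    if np.ptp(ax_sd) == 0 or np.ptp(ax_mean) == 0:
        warnings.warn("zero variance in the axon (predictor) statistic; R^2 undefined")
        return DispersionCorrelation(
            r_squared_sd=float("nan"), r_squared_mean=float("nan"),
            slope_sd=float("nan"), slope_mean=float("nan"),
            n_pairs=len(pairs), defined=False,
        )
    r2_sd, slope_sd = _ols_r2(ax_sd, as_sd)
    r2_mean, slope_mean = _ols_r2(ax_mean, as_mean)
    return DispersionCorrelation(
        r_squared_sd=r2_sd, r_squared_mean=r2_mean,
        slope_sd=slope_sd, slope_mean=slope_mean, n_pairs=len(pairs),
    )


def compare_regions(groups: dict[str, list[float]]) -> RegionComparison:
    """One-way ANOVA with Tukey HSD over region-wise dispersion values.

    ``groups`` maps region label -> list of per-image SD values.  Groups with
    fewer than 3 values are excluded with a warning.  Normality p-values
    (D'Agostino-Pearson) are reported per group where the sample is large
    enough for the test (n >= 8), else NaN.
    """
    usable = {}
    for name, vals in groups.items():
        vals = [float(v) for v in vals]
        if len(vals) < 3:
            warnings.warn(f"group {name!r} has <3 values; excluded from comparison")
            continue
        usable[name] = vals
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with >= 3 values each")
    names = sorted(usable)
    samples = [np.asarray(usable[n]) for n in names]
    F, p = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise.append((names[i], names[j], float(tukey.pvalue[i, j])))
    normality = {}
    for n, s in zip(names, samples):
        if len(s) >= 8:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normality[n] = float(stats.normaltest(s).pvalue)
        else:
            normality[n] = float("nan")
    return RegionComparison(
        groups=usable, anova_F=float(F), anova_p=float(p),
        pairwise=pairwise, normality_p_per_group=normality,
    )
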