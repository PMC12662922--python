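"""Image conditioning: SD Z-projection, CLAHE, and convex-hull tissue masking."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import exposure
from skimage.filters import threshold_otsu
from skimage.morphology import convex_hull_image

__all__ = ["ImageStack", "HullMask", "sd_project", "clahe", "convex_hull_mask"]


@dataclass
class ImageStack:
    """An ordered Z-stack of co-registered planes."""

    planes: np.ndarray  # (n_planes, h, w)
    pixel_size_um: float = 1.0

    def __post_init__(self):
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 3 or len(self.planes) < 1:
            raise ValueError("an ImageStack needs >= 1 same-shape 2-D planes")


@dataclass
class HullMask:
    """Convex mask of labeled tissue, with its polygon vertices (px, (x, y))."""

    mask: np.ndarray
    vertex_list: np.ndarray

    def apply(self, image: np.ndarray) -> np.ndarray:
        """Zero all pixels outside the hull of a co-registered channel."""
        if image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        out = image.copy()
        out[~self.mask] = 0
        return out


def _dtype_range(dtype) -> float:
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    return 1.0


def sd_project(stack: ImageStack, rescale: bool = True) -> np.ndarray:
    """Collapse a Z-stack to its per-pixel sample standard deviation.

    Uses the n-1 denominator; with ``rescale`` the SD image is mapped from
    [0, max SD] onto the input dtype's full range (the behaviour of an SD
    projection followed by display-range normalization).  SD projection
    highlights pixels whose intensity varies through depth — fibrous
    structure passing through the stack — over static background.
    """
    planes = stack.planes
    if len(planes) < 2:
        raise ValueError("SD projection needs >= 2 planes (n-1 denominator)")
    sd = np.std(planes.astype(np.float64), axis=0, ddof=1)
    if not rescale:
        return sd
    top = sd.max()
    out = sd / top * _dtype_range(planes.dtype) if top > 0 else sd
    if np.issubdtype(planes.dtype, np.integer):
        return np.round(out).astype(planes.dtype)
    return out.astype(planes.dtype)


def clahe(
    image: np.ndarray,
    clip_limit: float = 0.01,
    tile_size: int = 127,
    nbins: int = 256,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Defaults follow the common ImageJ plugin convention (127-px blocks,
    256 bins).  Output keeps the input's shape and dtype range.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("clahe expects a 2-D image")
    if tile_size > min(image.shape):
        raise ValueError(
            f"tile_size {tile_size} exceeds the smallest image dimension {min(image.shape)}"
        )
    if image.min() == image.max():
        return image.copy()  # flat histogram: equalization is the identity
    eq = exposure.equalize_adapthist(
        image, kernel_size=tile_size, clip_limit=clip_limit, nbins=nbins
    )
    out = eq * _dtype_range(image.dtype)
    if np.issubdtype(image.dtype, np.integer):
        return np.round(out).astype(image.dtype)
    return out.astype(image.dtype)


def convex_hull_mask(reference_channel: np.ndarray, binarize_method="otsu") -> HullMask:
    """Mask everything outside the convex hull of labeled tissue.

    ``binarize_method`` is ``"otsu"`` (global Otsu threshold), a numeric
    threshold, or a callable mapping the image to a boolean foreground.  The
    returned mask is the filled convex hull of the foreground pixels;
    applying it to a co-registered channel zeroes everything outside the
    labeled tissue.
    """
    ref = np.asarray(reference_channel)
    if ref.ndim != 2 or ref.size == 0:
        raise ValueError("reference channel must be a nonempty 2-D image")
    if callable(binarize_method):
        fg = np.asarray(binarize_method(ref), dtype=bool)
    elif binarize_method == "otsu":
        if ref.min() == ref.max():
            raise ValueError("no labeled tissue: reference channel is constant")
        fg = ref > threshold_otsu(ref)
    else:
        fg = ref > float(binarize_method)
    if not fg.any():
        raise ValueError("no labeled tissue: binarization left no foreground")
    coords = np.argwhere(fg)  # (row, col)
    pts = coords[:, ::-1].astype(float)  # (x, y)
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError(
            "labeled tissue needs >= 3 non-collinear foreground pixels"
        ) from exc
    vertices = pts[hull.vertices]
    mask = convex_hull_image(fg)
    return HullMask(mask=mask, vertex_list=vertices)
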