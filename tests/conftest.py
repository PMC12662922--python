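import numpy as np
import pytest

from fiberorient.phantom import _paint_stroke


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def render_line(
    angle_deg: float,
    *,
    size: int = 128,
    length_px: float = 100.0,
    fwhm_px: float = 3.0,
    amplitude: float = 200.0,
) -> np.ndarray:
    """A single Gaussian-profile line through the image centre (0-255 scale)."""
    img = np.zeros((size, size))
    sigma = fwhm_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    _paint_stroke(img, size / 2, size / 2, angle_deg, length_px, sigma, amplitude / 255.0)
    return img * 255.0


@pytest.fixture
def line_image():
    return render_line


def centerline_errors(points: np.ndarray, center, angle_deg: float) -> np.ndarray:
    """Perpendicular distances of contour points from an infinite line."""
    u = np.array([np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))])
    rel = points - np.asarray(center, float)
    t = rel @ u
    perp = rel - np.outer(t, u)
    return np.hypot(*perp.T)
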