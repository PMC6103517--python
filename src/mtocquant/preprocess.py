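"""Plane selection, projection, background subtraction, bleach correction.

These are the steps applied before any quantification: the brightest
tubulin plane defines the focal plane, a 3-slice sum projection around it is
the analysis image, slide background is the mean of three hand-drawn
rectangles, and time-lapse movies are photobleaching-corrected before comet
analysis.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import ImageStack, TimeLapse
from .geometry import Rect, rect_mean

log = logging.getLogger(__name__)


def select_focus_plane(stack: ImageStack, roi: Rect) -> int:
    """Index of the z-plane with the highest mean intensity inside ``roi``.

    Ties break toward the lower index (np.argmax's convention), so the
    result is deterministic on synthetic stacks with duplicated planes.
    """
    mask = roi.mask(stack.data.shape[1:], stack.pixel_size)
    if not mask.any():
        raise ValueError("focus ROI selects no pixels")
    means = stack.data[:, mask].mean(axis=1)
    return int(np.argmax(means))


def sum_project(stack: ImageStack, center: int, n_slices: int = 3) -> np.ndarray:
    """Pixelwise sum of ``n_slices`` planes centered on ``center``.

    The window is clipped at the stack boundaries rather than padded, so a
    projection centered on the first plane sums only the planes that exist.
    """
    if n_slices % 2 != 1 or n_slices < 1:
        raise ValueError("n_slices must be odd and positive")
    if not 0 <= center < stack.n_z:
        raise ValueError(f"center plane {center} out of range [0, {stack.n_z})")
    half = n_slices // 2
    lo = max(0, center - half)
    hi = min(stack.n_z, center + half + 1)
    return stack.data[lo:hi].sum(axis=0)


def estimate_slide_background(
    image: np.ndarray, bg_rects: list[Rect], pixel_size: float
) -> float:
    """Unweighted mean of the three slide-background rectangle means."""
    if len(bg_rects) < 3:
        raise ValueError("three slide-background rectangles are required")
    return float(np.mean([rect_mean(image, r, pixel_size) for r in bg_rects]))


def subtract_scalar(image: np.ndarray, value: float) -> np.ndarray:
    """Subtract a scalar background; negative values are retained, not clipped,
    so cohort means stay unbiased."""
    if not np.isfinite(value):
        raise ValueError("background value must be finite")
    return np.asarray(image, dtype=float) - value


def bleach_correct(movie: TimeLapse, method: str = "simple_ratio") -> TimeLapse:
    """Rescale each frame to undo photobleaching.

    ``simple_ratio`` scales every frame so its mean equals the first frame's
    mean (idempotent; corrected frame means are exactly constant).
    ``exponential_fit`` fits the frame-mean series to A·exp(−k·t) + B and
    divides each frame by its fitted decay relative to t = 0; if the fit
    fails it falls back to ``simple_ratio`` with a logged warning.
    """
    means = movie.data.mean(axis=(1, 2))
    if (means <= 0).any():
        raise ValueError("bleach correction requires positive frame means")
    if method == "simple_ratio":
        factors = means[0] / means
    elif method == "exponential_fit":
        if movie.n_frames < 3:
            raise ValueError("exponential_fit needs at least 3 frames")
        t = np.arange(movie.n_frames) * movie.frame_interval
        try:
            k0 = max(1e-3, -np.polyfit(t, np.log(np.clip(means, 1e-12, None)), 1)[0])
            popt, _ = curve_fit(
                lambda tt, a, k, b: a * np.exp(-k * tt) + b,
                t, means, p0=[means[0] - means[-1] + 1e-6, k0, means[-1]],
                maxfev=10000,
            )
            a, k, b = popt
            fitted = a * np.exp(-k * t) + b
            if (fitted <= 0).any():
                raise RuntimeError("fitted decay crosses zero")
            factors = fitted[0] / fitted
        except (RuntimeError, ValueError) as exc:
            log.warning("exponential bleach fit failed (%s); using simple_ratio", exc)
            factors = means[0] / means
    else:
        raise ValueError(f"unknown bleach-correction method {method!r}")
    corrected = movie.data * factors[:, None, None]
    return TimeLapse(corrected, movie.pixel_size, movie.frame_interval, movie.channel)
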