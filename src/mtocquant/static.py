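"""Still-image quantification: apical enrichment, percent depletion,
centrosomal ROI intensity, foci and nucleus counting.

Apical enrichment divides the slide-background-subtracted mean of a 2-μm
apical box by that of a 2-μm cytoplasmic box.  Percent depletion compares
degraded (gut(−)) embryos to their non-degraded gut(+) siblings after
correcting the gut-box mean (G) for out-of-focus external haze (X, a 2-μm
box outside the embryo) and gut autofluorescence (auto, measured on no-GFP
control embryos):

    signal     = mean_embryos(G − X) − auto          (per cohort)
    depletion% = 100 · (1 − signal_minus / signal_plus)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

from .datatypes import EmbryoAnnotation, ImageStack
from .geometry import circle_mask, rect_mean
from .preprocess import estimate_slide_background, select_focus_plane, subtract_scalar, sum_project

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    apical_mean: float
    cyto_mean: float
    ratio: float
    embryo_id: str = ""


@dataclass
class DepletionInputs:
    """Per-embryo gut (G) and external (X) box means plus the cohort
    autofluorescence scalar, all on slide-background-subtracted images."""

    g: np.ndarray
    x: np.ndarray
    auto: float


def apical_enrichment(
    image: np.ndarray,
    annotation: EmbryoAnnotation,
    slide_bg: float,
    pixel_size: float,
    embryo_id: str = "",
) -> EnrichmentResult:
    """Ratio of background-subtracted apical to cytoplasmic box means."""
    annotation.validate()
    a = rect_mean(image, annotation.apical_box, pixel_size) - slide_bg
    c = rect_mean(image, annotation.cyto_box, pixel_size) - slide_bg
    if c <= 0:
        raise ValueError(
            f"cytoplasmic mean {c:.3g} <= 0 after background subtraction; "
            "slide background appears over-subtracted"
        )
    return EnrichmentResult(float(a), float(c), float(a / c), embryo_id)


def percent_depletion(minus: DepletionInputs, plus: DepletionInputs) -> float:
    """Percent loss of gut marker signal in degraded embryos vs siblings."""
    if minus.g.size < 1 or plus.g.size < 1:
        raise ValueError("each cohort needs at least one embryo")
    signal_minus = float(np.mean(minus.g - minus.x) - minus.auto)
    signal_plus = float(np.mean(plus.g - plus.x) - plus.auto)
    if signal_plus <= 0:
        raise ValueError(
            f"gut(+) cohort signal {signal_plus:.3g} <= 0; depletion is undefined"
        )
    if signal_minus < 0:
        warnings.warn(
            "gut(−) cohort signal is negative; clamping to 0 (depletion capped at 100%)",
            stacklevel=2,
        )
        signal_minus = 0.0
    return 100.0 * (1.0 - signal_minus / signal_plus)


def project_and_subtract(
    stacks: dict[str, ImageStack], annotation: EmbryoAnnotation, n_slices: int = 3
) -> tuple[np.ndarray, float]:
    """Standard still-image preprocessing for one embryo.

    Selects the brightest tubulin plane inside the gut box, sum-projects
    ``n_slices`` marker planes around it, estimates slide background from the
    three background rectangles of the projected image and subtracts it.
    Returns the background-subtracted projection and the background value.
    """
    ps = stacks["marker"].pixel_size
    focus = select_focus_plane(stacks["tubulin"], annotation.gut_box)
    proj = sum_project(stacks["marker"], focus, n_slices)
    bg = estimate_slide_background(proj, annotation.bg_rects, ps)
    return subtract_scalar(proj, bg), bg


def depletion_inputs_from_cohort(
    embryos: list[tuple[dict[str, ImageStack], EmbryoAnnotation]],
    controls: list[tuple[dict[str, ImageStack], EmbryoAnnotation]],
) -> DepletionInputs:
    """Measure G and X per embryo and the autofluorescence scalar from controls."""
    auto_vals = []
    for stacks, ann in controls:
        img, _ = project_and_subtract(stacks, ann)
        auto_vals.append(rect_mean(img, ann.gut_box, stacks["marker"].pixel_size))
    auto = float(np.mean(auto_vals)) if auto_vals else 0.0

    g, x = [], []
    for stacks, ann in embryos:
        img, _ = project_and_subtract(stacks, ann)
        ps = stacks["marker"].pixel_size
        g.append(rect_mean(img, ann.gut_box, ps))
        x.append(rect_mean(img, ann.external_box, ps))
    return DepletionInputs(np.asarray(g), np.asarray(x), auto)


def centrosome_intensity(
    stack: ImageStack,
    center_rc: tuple[float, float],
    diameter_px: float = 7.0,
    slide_bg: float = 0.0,
) -> float:
    """Background-subtracted mean in a circular ROI at the brightest z-plane.

    The circle contains the pixels whose centers lie within diameter/2 of
    ``center_rc`` (row, col, pixel units); for the default 7-pixel diameter
    centered on a pixel that is 37 pixels.  The z-plane maximizing the ROI
    mean is selected first.
    """
    radius = diameter_px / 2.0
    rows, cols = stack.data.shape[1:]
    r, c = center_rc
    if r - radius < -0.5 or c - radius < -0.5 or r + radius > rows - 0.5 or c + radius > cols - 0.5:
        raise ValueError("circular ROI is clipped by the image border")
    mask = circle_mask((rows, cols), center_rc, radius)
    means = stack.data[:, mask].mean(axis=1)
    return float(means.max() - slide_bg)


def count_foci(
    image: np.ndarray,
    pixel_size: float,
    min_separation: float = 1.0,
    sigma: float = 0.2,
    k_sd: float = 5.0,
    region: np.ndarray | None = None,
) -> tuple[int, np.ndarray]:
    """Count bright puncta by smoothed local maxima above a robust threshold.

    The image is Gaussian-smoothed at ``sigma`` (μm), the background level
    and spread are taken as the median and 1.4826·MAD of the smoothed image,
    and local maxima above median + ``k_sd``·SD are kept; maxima closer than
    ``min_separation`` are merged, keeping the brighter.  ``region`` is an
    optional boolean mask (e.g. the intestinal primordium): the robust
    background statistics are computed inside it and peaks outside it are
    ignored, so the step between tissue and slide background is not mistaken
    for signal.  Returns the count and the peak coordinates in pixel
    (row, col) units.
    """
    if min_separation <= 0 or sigma <= 0 or k_sd <= 0:
        raise ValueError("detection parameters must be positive")
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        return 0, np.empty((0, 2))
    sm = gaussian_filter(img, sigma / pixel_size)
    ref = sm[region] if region is not None else sm
    med = float(np.median(ref))
    mad = float(np.median(np.abs(ref - med)))
    robust_sd = 1.4826 * mad
    thr = med + k_sd * robust_sd + 1e-6 * max(1.0, abs(med))
    peaks = peak_local_max(
        sm,
        min_distance=max(1, int(round(min_separation / pixel_size))),
        threshold_abs=thr,
        exclude_border=False,
    )
    if region is not None and len(peaks):
        keep = region[peaks[:, 0], peaks[:, 1]]
        peaks = peaks[keep]
    return len(peaks), peaks.astype(float)


def count_nuclei(
    image: np.ndarray,
    pixel_size: float,
    min_separation: float = 1.0,
    sigma: float = 0.4,
    k_sd: float = 5.0,
    region: np.ndarray | None = None,
) -> tuple[int, np.ndarray]:
    """Nucleus counting: the foci detector with a wider smoothing preset."""
    return count_foci(image, pixel_size, min_separation, sigma, k_sd, region)
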