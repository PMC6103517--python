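"""Line-intensity profiles across the apical midline.

A 1-μm-wide band is drawn across the midline and every pixel within 5 μm
of it is binned by signed perpendicular distance (one bin per pixel of
distance).  Cohort summaries average profiles across embryos, optionally
normalizing each profile by its own cytoplasmic mean (used for
array-expressed tubulin, whose expression level varies between embryos; not
used for endogenous markers), and locate the apical peak region by the
half-max rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Segment

CYTO_REGION_UM = (2.5, 5.0)


@dataclass
class LineProfile:
    """Per-embryo intensity vs signed distance from the midline.

    ``d`` holds bin centers in μm (negative = left of the directed
    midline); ``intensity`` the mean over pixels whose centers fall in the
    1-μm-wide band and that bin's distance slab.
    """

    d: np.ndarray
    intensity: np.ndarray
    embryo_id: str = ""

    @property
    def cyto_mask(self) -> np.ndarray:
        a = np.abs(self.d)
        return (a >= CYTO_REGION_UM[0]) & (a <= CYTO_REGION_UM[1])

    @property
    def mean_cyto(self) -> float:
        return float(np.nanmean(self.intensity[self.cyto_mask]))


@dataclass
class ProfileSummary:
    """Cohort-averaged profile with per-embryo peak/cytoplasmic means."""

    d: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int
    peak_region: tuple[float, float] | None
    per_embryo: pd.DataFrame  # embryo_id, mean_peak, mean_cyto
    normalized: bool


def line_profile(
    image: np.ndarray,
    midline: Segment,
    pixel_size: float,
    width: float = 1.0,
    max_dist: float = 5.0,
    embryo_id: str = "",
) -> LineProfile:
    """Bin pixels of a 1-μm band across the midline by signed distance.

    The band is centered on the midline midpoint: pixels whose axial
    coordinate lies within ``width``/2 of the midpoint and whose signed
    perpendicular distance is within ±``max_dist``.  Bin width is one pixel.
    """
    if midline.length < width:
        raise ValueError("midline segment must be at least as long as the band width")
    rows, cols = image.shape
    _check_band_inside(midline, pixel_size, width, max_dist, rows, cols)

    y = np.arange(rows)[:, None] * pixel_size
    x = np.arange(cols)[None, :] * pixel_size
    d = midline.signed_distance(x, y)
    t = midline.axial_coordinate(x, y)
    t_mid = midline.length / 2.0

    n_bins = int(round(2 * max_dist / pixel_size))
    edges = -max_dist + pixel_size * np.arange(n_bins + 1)
    in_band = (np.abs(t - t_mid) <= width / 2.0) & (d >= -max_dist) & (d <= max_dist)
    idx = np.clip(((d - edges[0]) / pixel_size).astype(int), 0, n_bins - 1)

    sums = np.bincount(idx[in_band], weights=image[in_band], minlength=n_bins)
    counts = np.bincount(idx[in_band], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = edges[:-1] + pixel_size / 2.0
    return LineProfile(centers, means, embryo_id)


def _check_band_inside(
    midline: Segment, pixel_size: float, width: float, max_dist: float,
    rows: int, cols: int,
) -> None:
    u = midline.direction
    n = np.array([-u[1], u[0]])
    c = midline.midpoint
    corners = [
        c + a * (width / 2.0) * u + b * max_dist * n
        for a in (-1, 1) for b in (-1, 1)
    ]
    xmax = (cols - 1) * pixel_size
    ymax = (rows - 1) * pixel_size
    bad = [p for p in corners if not (0 <= p[0] <= xmax and 0 <= p[1] <= ymax)]
    if bad:
        raise ValueError(
            f"profile band exits the image bounds at {[tuple(np.round(p, 3)) for p in bad]}"
        )


def summarize_profiles(
    profiles: list[LineProfile], normalize: bool = False
) -> ProfileSummary:
    """Cohort mean ± SD profile, per-embryo peak/cyto means, half-max peak region.

    The peak region is computed on the cohort mean profile: all bins whose
    intensity reaches halfway between the mean cytoplasmic value and the
    maximum, taking the connected run of bins containing the maximum.  A
    flat cohort profile has no peak; ``peak_region`` is then None rather
    than fabricated.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    d = profiles[0].d
    for p in profiles[1:]:
        if p.d.shape != d.shape or not np.allclose(p.d, d):
            raise ValueError("profiles must share an identical bin grid")

    mat = np.stack([
        p.intensity / p.mean_cyto if normalize else p.intensity for p in profiles
    ])
    with warnings.catch_warnings():
        # bins that are empty in every profile stay NaN without complaint
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1) if len(profiles) > 1 else np.zeros_like(mean)

    cyto_mask = profiles[0].cyto_mask
    mean_cyto_of_mean = float(np.nanmean(mean[cyto_mask]))
    peak_val = float(np.nanmax(mean))
    peak_region = None
    peak_mask = np.zeros_like(mean, dtype=bool)
    if peak_val > mean_cyto_of_mean + 1e-12 * max(1.0, abs(peak_val)):
        thr = mean_cyto_of_mean + 0.5 * (peak_val - mean_cyto_of_mean)
        above = np.nan_to_num(mean, nan=-np.inf) >= thr
        imax = int(np.nanargmax(mean))
        lo = imax
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = imax
        while hi < len(mean) - 1 and above[hi + 1]:
            hi += 1
        peak_mask[lo:hi + 1] = True
        peak_region = (float(d[lo]), float(d[hi]))

    rows = []
    for p, prof in zip(mat, profiles):
        rows.append({
            "embryo_id": prof.embryo_id,
            "mean_peak": float(np.nanmean(p[peak_mask])) if peak_mask.any() else np.nan,
            "mean_cyto": float(np.nanmean(p[cyto_mask])),
        })
    return ProfileSummary(
        d=d, mean=mean, sd=sd, n=len(profiles), peak_region=peak_region,
        per_embryo=pd.DataFrame(rows), normalized=normalize,
    )
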