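"""Planar geometry for ROI measurement.

Conventions used throughout the package:

* physical coordinates are in micrometres (μm), with ``x`` along image
  columns and ``y`` along image rows;
* pixel centers sit at integer pixel indices, so the center of pixel
  ``(row, col)`` is at ``(x, y) = (col * pixel_size, row * pixel_size)``;
* all distances are measured center-to-center;
* rectangles are axis-aligned and closed: a pixel belongs to a rectangle
  when its center satisfies ``x0 <= x <= x1`` and ``y0 <= y <= y1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in μm: [x0, x1] x [y0, y1]."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate rectangle {self}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    def mask(self, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
        """Boolean mask of pixels whose centers fall inside the rectangle."""
        rows, cols = shape
        y = np.arange(rows)[:, None] * pixel_size
        x = np.arange(cols)[None, :] * pixel_size
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    def contains_rect(self, other: "Rect") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and self.x1 >= other.x1
            and self.y1 >= other.y1
        )

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "x1": self.x1, "y1": self.y1}

    @classmethod
    def from_dict(cls, d: dict) -> "Rect":
        return cls(d["x0"], d["y0"], d["x1"], d["y1"])


def rect_mean(image: np.ndarray, rect: Rect, pixel_size: float) -> float:
    """Mean intensity over pixels whose centers lie inside ``rect``.

    Raises if the rectangle selects no pixel or extends past the image.
    """
    rows, cols = image.shape[-2:]
    if rect.x0 < -0.5 * pixel_size or rect.y0 < -0.5 * pixel_size:
        raise ValueError(f"rectangle {rect} extends past the image origin")
    if rect.x1 > (cols - 0.5) * pixel_size or rect.y1 > (rows - 0.5) * pixel_size:
        raise ValueError(f"rectangle {rect} extends past the image bounds")
    m = rect.mask((rows, cols), pixel_size)
    if not m.any():
        raise ValueError(f"rectangle {rect} contains no pixel centers")
    return float(image[..., m].mean())


@dataclass(frozen=True)
class Segment:
    """Directed line segment in μm from (x0, y0) to (x1, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def length(self) -> float:
        return float(np.hypot(self.x1 - self.x0, self.y1 - self.y0))

    @property
    def direction(self) -> np.ndarray:
        d = np.array([self.x1 - self.x0, self.y1 - self.y0])
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("zero-length segment has no direction")
        return d / n

    @property
    def midpoint(self) -> np.ndarray:
        return np.array([(self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0])

    def signed_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Signed perpendicular distance from the directed line through the segment.

        In image coordinates (y increasing downwards) a point with negative
        signed distance lies to the left of the direction of travel.
        """
        u = self.direction
        wx = np.asarray(x, dtype=float) - self.x0
        wy = np.asarray(y, dtype=float) - self.y0
        # z-component of u x w; sign flips with the image-axis handedness
        return u[0] * wy - u[1] * wx

    def axial_coordinate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Projection onto the segment direction, 0 at the first endpoint."""
        u = self.direction
        wx = np.asarray(x, dtype=float) - self.x0
        wy = np.asarray(y, dtype=float) - self.y0
        return u[0] * wx + u[1] * wy

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "x1": self.x1, "y1": self.y1}

    @classmethod
    def from_dict(cls, d: dict) -> "Segment":
        return cls(d["x0"], d["y0"], d["x1"], d["y1"])


def circle_mask(
    shape: tuple[int, int], center_rc: tuple[float, float], radius_px: float
) -> np.ndarray:
    """Pixels whose centers lie within ``radius_px`` (inclusive) of the center.

    ``center_rc`` is (row, col) in pixel units.  For the 7-pixel-diameter
    centrosomal ROI (radius 3.5 px) centered on a pixel this selects 37
    pixels.
    """
    rows, cols = shape
    r = np.arange(rows)[:, None] - center_rc[0]
    c = np.arange(cols)[None, :] - center_rc[1]
    return r * r + c * c <= radius_px * radius_px


def clip_segment_to_rect(seg: Segment, rect: Rect) -> Segment:
    """Clip a directed segment to an axis-aligned rectangle (Liang-Barsky)."""
    p0 = np.array([seg.x0, seg.y0])
    d = np.array([seg.x1 - seg.x0, seg.y1 - seg.y0])
    t0, t1 = 0.0, 1.0
    for dim, (lo, hi) in enumerate([(rect.x0, rect.x1), (rect.y0, rect.y1)]):
        if d[dim] == 0:
            if p0[dim] < lo or p0[dim] > hi:
                raise ValueError("segment lies outside the clipping rectangle")
            continue
        ta = (lo - p0[dim]) / d[dim]
        tb = (hi - p0[dim]) / d[dim]
        ta, tb = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, ta), min(t1, tb)
    if t0 >= t1:
        raise ValueError("segment lies outside the clipping rectangle")
    a = p0 + t0 * d
    b = p0 + t1 * d
    return Segment(float(a[0]), float(a[1]), float(b[0]), float(b[1]))
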