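"""Core data containers: imaging geometry, ground truth, annotations, images.

The containers mirror how the measurements are organised: an embryo is
imaged as a two-channel z-stack (GFP-tagged marker plus an mCherry::tubulin
reference used only to find the intestinal midline) or as a single-channel
time-lapse movie, and every measurement ROI (midline segment, gut /
external / apical / cytoplasmic boxes, slide-background rectangles) is an
annotation in physical μm coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import Rect, Segment


@dataclass(frozen=True)
class SceneParams:
    """Imaging geometry of one synthetic field of view.

    Lengths in μm, times in seconds.  ``image_shape`` is (rows, cols).
    ``frame_interval`` is only required when generating movies.
    """

    primordium_length: float = 14.0
    primordium_half_width: float = 5.5
    pixel_size: float = 0.11
    z_step: float = 0.5
    frame_interval: float | None = 0.1
    image_shape: tuple[int, int] = (256, 256)
    field_margin: float = 2.5
    n_z: int = 7
    z_sigma: float = 1.0  # axial extent of the in-focus signal, μm

    def __post_init__(self) -> None:
        for name in ("primordium_length", "primordium_half_width", "pixel_size",
                     "z_step", "field_margin", "z_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.frame_interval is not None and self.frame_interval <= 0:
            raise ValueError("frame_interval must be strictly positive")
        if min(self.image_shape) < 8 or self.n_z < 1:
            raise ValueError("image_shape / n_z too small")
        fy = self.field_height
        fx = self.field_width
        if self.primordium_length > fy - 2 * self.field_margin:
            raise ValueError("primordium does not fit inside the image minus margin")
        if 2 * self.primordium_half_width > fx - 2 * self.field_margin:
            raise ValueError("primordium does not fit inside the image minus margin")

    @property
    def field_width(self) -> float:
        return (self.image_shape[1] - 1) * self.pixel_size

    @property
    def field_height(self) -> float:
        return (self.image_shape[0] - 1) * self.pixel_size


@dataclass(frozen=True)
class NoiseParams:
    """EM-CCD noise model: Poisson(gain * mean) / gain + N(0, read_sd)."""

    poisson_gain: float = 1.0
    read_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.poisson_gain < 0 or self.read_sd < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Hidden parameters of a synthetic embryo; the quantities the pipeline estimates.

    ``enrichment_ratio`` is the apical plateau over the cytoplasmic plateau
    of the background-free marker profile; ``depletion_fraction`` scales the
    gut marker component of degraded (gut(−)) embryos by (1 − δ);
    ``haze_level`` is the uniform out-of-focus additive term contributed by
    non-degraded protein in neighbouring tissues; ``autofluo_level`` is the
    gut-restricted autofluorescence; ``comet_emission`` is the expected
    number of comets crossing one 5-μm line at 3 μm offset per 10 s.
    """

    enrichment_ratio: float = 1.67
    cyto_level: float = 100.0
    depletion_fraction: float = 0.0
    haze_level: float = 0.0
    autofluo_level: float = 0.0
    slide_bg: float = 10.0
    comet_speed: float = 0.558
    comet_emission: float = 6.0
    comet_amplitude: float = 150.0
    comet_sigma: float = 0.15
    comet_angle_sd: float = 6.0  # splay of tracks about the outward normal, degrees
    foci_count: int = 0
    nucleus_count: int = 0
    bleach_rate: float = 0.0
    embryo_cv: float = 0.05  # embryo-to-embryo variability of cyto_level
    tub_cyto_level: float = 100.0
    tub_enrichment: float = 3.0
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if self.enrichment_ratio < 1:
            raise ValueError("enrichment_ratio must be >= 1")
        if not 0 <= self.depletion_fraction <= 1:
            raise ValueError("depletion_fraction must lie in [0, 1]")
        for name in ("comet_speed", "comet_emission", "bleach_rate",
                     "haze_level", "autofluo_level", "slide_bg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.foci_count < 0 or self.nucleus_count < 0:
            raise ValueError("counts must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EmbryoAnnotation:
    """All named measurement ROIs for one embryo, in μm.

    The apical and cytoplasmic boxes are 2 μm wide, the gut box 10 μm wide;
    the external box lies in the embryo-free field margin and the three
    slide-background rectangles lie outside the embryo.
    """

    midline: Segment
    gut_box: Rect
    external_box: Rect
    apical_box: Rect
    cyto_box: Rect
    bg_rects: list[Rect]
    foci_centers: list[tuple[float, float]] | None = None
    nucleus_centers: list[tuple[float, float]] | None = None

    def validate(self, tol: float = 1e-6) -> None:
        if abs(self.apical_box.width - 2.0) > tol or abs(self.cyto_box.width - 2.0) > tol:
            raise ValueError("apical and cytoplasmic boxes must be 2 μm wide")
        if abs(self.gut_box.width - 10.0) > tol:
            raise ValueError("gut box must be 10 μm wide")
        if len(self.bg_rects) != 3:
            raise ValueError("exactly three slide-background rectangles are required")

    def to_dict(self) -> dict:
        d = {
            "midline": self.midline.to_dict(),
            "gut_box": self.gut_box.to_dict(),
            "external_box": self.external_box.to_dict(),
            "apical_box": self.apical_box.to_dict(),
            "cyto_box": self.cyto_box.to_dict(),
            "bg_rects": [r.to_dict() for r in self.bg_rects],
            "units": "um",
        }
        if self.foci_centers is not None:
            d["foci_centers"] = [list(p) for p in self.foci_centers]
        if self.nucleus_centers is not None:
            d["nucleus_centers"] = [list(p) for p in self.nucleus_centers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EmbryoAnnotation":
        return cls(
            midline=Segment.from_dict(d["midline"]),
            gut_box=Rect.from_dict(d["gut_box"]),
            external_box=Rect.from_dict(d["external_box"]),
            apical_box=Rect.from_dict(d["apical_box"]),
            cyto_box=Rect.from_dict(d["cyto_box"]),
            bg_rects=[Rect.from_dict(r) for r in d["bg_rects"]],
            foci_centers=[tuple(p) for p in d["foci_centers"]] if "foci_centers" in d else None,
            nucleus_centers=[tuple(p) for p in d["nucleus_centers"]] if "nucleus_centers" in d else None,
        )


@dataclass
class ImageStack:
    """A calibrated single-channel z-stack: data is (z, rows, cols)."""

    data: np.ndarray
    pixel_size: float
    z_step: float
    channel: str = "marker"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("ImageStack data must be 3-D (z, rows, cols)")
        if not np.isfinite(self.data).all():
            raise ValueError("intensities must be finite")
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise ValueError("pixel_size and z_step must be positive")

    @property
    def n_z(self) -> int:
        return self.data.shape[0]


@dataclass
class TimeLapse:
    """A calibrated single-channel movie: data is (t, rows, cols)."""

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    channel: str = "marker"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("TimeLapse data must be 3-D (t, rows, cols)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval
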