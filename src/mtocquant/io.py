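"""Disk formats: multi-page TIFF with plain-text sidecar metadata,
annotation / ground-truth JSON (units in μm), and CSV event logs.

A z-stack or movie is written as one single-channel multi-page TIFF (one
page per z or per t) next to a ``<name>.meta.txt`` key-value header holding
pixel_size, z_step or frame_interval, and the channel label, so plain TIFF
viewers and the pipeline read the same files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import EmbryoAnnotation, GroundTruth, ImageStack, TimeLapse


def _write_sidecar(path: Path, meta: dict) -> None:
    lines = [f"{k} = {v}" for k, v in meta.items()]
    path.write_text("\n".join(lines) + "\n")


def _read_sidecar(path: Path) -> dict:
    meta = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32))
    _write_sidecar(path.with_suffix(".meta.txt"), {
        "kind": "zstack",
        "pixel_size_um": stack.pixel_size,
        "z_step_um": stack.z_step,
        "channel": stack.channel,
    })
    return path


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    meta = _read_sidecar(path.with_suffix(".meta.txt"))
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(
        data, float(meta["pixel_size_um"]), float(meta["z_step_um"]),
        meta.get("channel", "marker"),
    )


def write_movie(movie: TimeLapse, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, movie.data.astype(np.float32))
    _write_sidecar(path.with_suffix(".meta.txt"), {
        "kind": "timelapse",
        "pixel_size_um": movie.pixel_size,
        "frame_interval_s": movie.frame_interval,
        "channel": movie.channel,
    })
    return path


def read_movie(path: str | Path) -> TimeLapse:
    path = Path(path)
    meta = _read_sidecar(path.with_suffix(".meta.txt"))
    return TimeLapse(
        tifffile.imread(path), float(meta["pixel_size_um"]),
        float(meta["frame_interval_s"]), meta.get("channel", "marker"),
    )


def write_annotation(ann: EmbryoAnnotation, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(ann.to_dict(), indent=2) + "\n")
    return path


def read_annotation(path: str | Path) -> EmbryoAnnotation:
    return EmbryoAnnotation.from_dict(json.loads(Path(path).read_text()))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=2) + "\n")
    return path


def write_event_log(log: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in ["time_s", "side", "lateral_um", "speed_um_s", "angle_deg"]
            if c in log.columns]
    log[cols].to_csv(path, index=False)
    return path
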