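#!/usr/bin/env python
"""Render one example of every synthetic scene and write it to disk.

Produces a two-channel primordium z-stack, a depletion sibling pair, a
comet time-lapse with its birth event log, and a foci image — each with
its annotation and hidden ground truth.  TIFF pixel data goes under
scratch/ (bulky); annotations, ground truth and event logs (the analysis
inputs) go under results/synthetic_examples/.
"""

from pathlib import Path

from mtocquant.datatypes import GroundTruth
from mtocquant.experiments import MOVIE_SCENE, STILL_SCENE
from mtocquant.io import (
    write_annotation,
    write_event_log,
    write_ground_truth,
    write_movie,
    write_stack,
)
from mtocquant.synthetic import generate_comet_movie, generate_foci_image, generate_primordium_image

SEED = 20260301
SCRATCH = Path("scratch/synthetic_examples")
OUT = Path("results/synthetic_examples")


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    OUT.mkdir(parents=True, exist_ok=True)

    truth = GroundTruth(enrichment_ratio=1.67, haze_level=30.0, autofluo_level=15.0)
    stacks, ann, _ = generate_primordium_image(STILL_SCENE, truth, SEED)
    for channel, stack in stacks.items():
        write_stack(stack, SCRATCH / f"primordium_{channel}.tif")
    write_annotation(ann, OUT / "primordium_annotation.json")
    write_ground_truth(truth, OUT / "primordium_truth.json")

    movie_truth = GroundTruth(comet_speed=0.558, comet_emission=5.55)
    movie, mann, _, log = generate_comet_movie(MOVIE_SCENE, movie_truth, 10.0, SEED)
    write_movie(movie, SCRATCH / "comet_movie.tif")
    write_annotation(mann, OUT / "movie_annotation.json")
    write_event_log(log, OUT / "movie_events.csv")
    write_ground_truth(movie_truth, OUT / "movie_truth.json")

    foci_truth = GroundTruth(foci_count=3)
    stack, fann = generate_foci_image(STILL_SCENE, foci_truth, SEED)
    write_stack(stack, SCRATCH / "foci.tif")
    write_annotation(fann, OUT / "foci_annotation.json")

    print(f"wrote example TIFFs to {SCRATCH}/ and sidecar records to {OUT}/")
    print(f"comet movie: {len(log)} births, {movie.n_frames} frames, "
          f"{movie.pixel_size} um/px")


if __name__ == "__main__":
    main()
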