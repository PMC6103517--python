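"""End-to-end parameter-recovery workflows.

Each function generates a synthetic cohort at a stated ground-truth
operating point, runs the full measurement pipeline on it (never touching
the hidden truth), and returns per-embryo tables plus a cohort summary.
These are the workhorses behind the analysis scripts and the acceptance
checks: recovery is judged by whether the measured cohort mean falls within
3 standard errors of the generating truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .datatypes import GroundTruth, SceneParams
from .dynamics import count_crossings, embryo_mean_speed, measure_comet_speeds, track_movie
from .preprocess import bleach_correct
from .profiles import line_profile, summarize_profiles
from .static import apical_enrichment, depletion_inputs_from_cohort, percent_depletion, project_and_subtract
from .synthetic import (
    generate_comet_movie,
    generate_depletion_cohort,
    generate_primordium_image,
)

#: Scene for 100x comet time-lapse acquisition (0.1-s frames for 10 s).
MOVIE_SCENE = SceneParams(image_shape=(192, 192), frame_interval=0.1)

#: Scene for still z-stack acquisition.
STILL_SCENE = SceneParams(image_shape=(256, 256), frame_interval=None)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def run_enrichment_recovery(
    truth: GroundTruth,
    n_embryos: int = 15,
    seed: int = 0,
    scene: SceneParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Recover the apical enrichment ratio from a cohort of still images.

    Per embryo: brightest-tubulin-plane selection, 3-slice sum projection,
    slide-background subtraction, then the 2-μm apical/cytoplasmic box
    ratio.  Also builds the cohort line-profile summary.
    """
    scene = scene or STILL_SCENE
    var_rng = np.random.default_rng(seed)
    rows, profiles = [], []
    for i, s in enumerate(_spawn_seeds(seed + 1, n_embryos)):
        factor = max(0.1, 1.0 + truth.embryo_cv * var_rng.standard_normal())
        t = dataclasses.replace(truth, cyto_level=truth.cyto_level * factor)
        stacks, ann, _ = generate_primordium_image(scene, t, s)
        img, bg = project_and_subtract(stacks, ann)
        res = apical_enrichment(img, ann, 0.0, scene.pixel_size, embryo_id=f"e{i:02d}")
        profiles.append(line_profile(img, ann.midline, scene.pixel_size, embryo_id=f"e{i:02d}"))
        rows.append({
            "embryo_id": f"e{i:02d}", "apical_mean": res.apical_mean,
            "cyto_mean": res.cyto_mean, "ratio": res.ratio, "slide_bg": bg,
        })
    df = pd.DataFrame(rows)
    ratios = df["ratio"].to_numpy()
    summary = {
        "mean_ratio": float(ratios.mean()),
        "sd": float(ratios.std(ddof=1)) if n_embryos > 1 else 0.0,
        "se": float(ratios.std(ddof=1) / np.sqrt(n_embryos)) if n_embryos > 1 else 0.0,
        "n": n_embryos,
        "truth": truth.enrichment_ratio,
        "profile_summary": summarize_profiles(profiles, normalize=False),
    }
    return df, summary


def run_depletion_recovery(
    truth: GroundTruth,
    n_minus: int = 12,
    n_plus: int = 12,
    n_controls: int = 5,
    seed: int = 0,
    scene: SceneParams | None = None,
) -> dict:
    """Recover percent depletion from gut(−)/gut(+) sibling cohorts.

    The standard error of the recovered percentage is obtained by
    leave-one-out jackknife over the embryos of both cohorts.
    """
    scene = scene or STILL_SCENE
    minus, plus, controls, _ = generate_depletion_cohort(
        scene, truth, n_minus, n_plus, seed, n_controls
    )
    d_minus = depletion_inputs_from_cohort(minus, controls)
    d_plus = depletion_inputs_from_cohort(plus, controls)
    pct = percent_depletion(d_minus, d_plus)

    # jackknife over embryos for a cohort-level SE
    reps = []
    for i in range(n_minus):
        dm = dataclasses.replace(d_minus)
        dm = type(d_minus)(np.delete(d_minus.g, i), np.delete(d_minus.x, i), d_minus.auto)
        reps.append(percent_depletion(dm, d_plus))
    for i in range(n_plus):
        dp = type(d_plus)(np.delete(d_plus.g, i), np.delete(d_plus.x, i), d_plus.auto)
        reps.append(percent_depletion(d_minus, dp))
    reps = np.asarray(reps)
    m = len(reps)
    se = float(np.sqrt((m - 1) / m * ((reps - reps.mean()) ** 2).sum()))
    return {
        "percent_depletion": float(pct),
        "se": se,
        "truth_percent": 100.0 * truth.depletion_fraction,
        "inputs_minus": d_minus,
        "inputs_plus": d_plus,
    }


def run_speed_recovery(
    truth: GroundTruth,
    n_embryos: int = 10,
    seed: int = 0,
    source: str = "midline",
    context: str = "E16",
    duration: float = 10.0,
    min_births: int = 3,
    scene: SceneParams | None = None,
    bleach_method: str | None = "simple_ratio",
) -> tuple[pd.DataFrame, dict]:
    """Recover mean comet speed via the kymograph pipeline.

    Per embryo: generate a movie, bleach-correct, track comets, build one
    5-pixel-wide kymograph per trajectory, fit streak slopes, apply the
    >= 2-comet per-embryo rule, then average embryo means.  Intestinal
    embryos use ``source='midline'``/``context='E16'``; centrosomal ones use
    ``source='point'`` with the two-cell exclusion rule.
    """
    scene = scene or MOVIE_SCENE
    rows = []
    for i, s in enumerate(_spawn_seeds(seed, n_embryos)):
        movie, ann, _, _ = generate_comet_movie(
            scene, truth, duration, s, source=source, min_births=min_births
        )
        if bleach_method is not None and truth.bleach_rate > 0:
            movie = bleach_correct(movie, bleach_method)
        if source == "point":
            center = ((scene.image_shape[1] - 1) / 2.0 * scene.pixel_size,
                      (scene.image_shape[0] - 1) / 2.0 * scene.pixel_size)
            exclusion = (center, 1.0)
        else:
            exclusion = (ann.midline, 1.0)
        # slopes are read only from streaks with >= 12 clean rows (1.2 s):
        # shorter reads are dominated by crowding residuals
        speeds_df = measure_comet_speeds(movie, exclusion=exclusion,
                                         min_streak_frames=12)
        emb = embryo_mean_speed(list(speeds_df["speed_um_s"]), context=context)
        rows.append({
            "embryo_id": f"e{i:02d}",
            "n_comets": len(speeds_df),
            "mean_speed": emb.mean_speed if emb.mean_speed is not None else np.nan,
            "status": emb.status,
        })
    df = pd.DataFrame(rows)
    ok = df[df["status"] == "ok"]["mean_speed"].to_numpy()
    summary = {
        "mean_of_embryo_means": float(ok.mean()) if len(ok) else np.nan,
        "sd": float(ok.std(ddof=1)) if len(ok) > 1 else 0.0,
        "se": float(ok.std(ddof=1) / np.sqrt(len(ok))) if len(ok) > 1 else np.nan,
        "n_embryos": int(len(ok)),
        "n_comets_total": int(df["n_comets"].sum()),
        "truth": truth.comet_speed,
    }
    return df, summary


def run_crossing_recovery(
    truth: GroundTruth,
    n_embryos: int = 20,
    seed: int = 0,
    duration: float = 10.0,
    scene: SceneParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Recover the per-embryo comet crossing count (both 5-μm lines, 10 s)."""
    scene = scene or MOVIE_SCENE
    rows = []
    for i, s in enumerate(_spawn_seeds(seed, n_embryos)):
        movie, ann, _, _ = generate_comet_movie(scene, truth, duration, s)
        trajs = track_movie(movie)
        left, right, total = count_crossings(movie, ann.midline, trajectories=trajs)
        rows.append({"embryo_id": f"e{i:02d}", "left": left, "right": right, "total": total})
    df = pd.DataFrame(rows)
    totals = df["total"].to_numpy(dtype=float)
    summary = {
        "mean_total": float(totals.mean()),
        "sd": float(totals.std(ddof=1)) if n_embryos > 1 else 0.0,
        "se": float(totals.std(ddof=1) / np.sqrt(n_embryos)) if n_embryos > 1 else 0.0,
        "n_embryos": n_embryos,
        "truth_total": 2.0 * truth.comet_emission,
    }
    return df, summary
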