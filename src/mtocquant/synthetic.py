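"""Synthetic fluorescence microscopy of the polarized intestinal primordium.

Every generator hides a :class:`~mtocquant.datatypes.GroundTruth` inside its
output so each downstream measurement (enrichment, percent depletion, comet
speed, crossing counts, foci counts) can be validated by parameter recovery
without any external data.

The still-image model
---------------------
The primordium is a band of half-width ``w`` around a straight apical
midline of length ``L``.  With ``d`` the signed perpendicular distance from
the midline, the noiseless marker-channel mean of the in-focus plane is::

    slide_bg + haze + [inside gut] * (auto + C * g(d))

where ``g(d) = r`` for |d| <= 1 μm (apical plateau), ``g(d) = 1`` for
|d| >= 2.5 μm (cytoplasmic plateau) and linear in between.  The piecewise
profile makes the 2-μm apical/cytoplasmic box estimator recover ``r``
exactly in the noiseless case.  The haze term (out-of-focus light from
non-degraded protein in neighbouring tissues) is uniform over the field;
the autofluorescence term is gut-restricted.  The tubulin reference channel
shares the profile shape so midline-finding logic can be exercised on it.

A z-stack is built by scaling the embryo component by a Gaussian axial
weight so the central slice is brightest; slide background and haze are
z-independent.  Noise is Poisson shot noise at a configurable gain plus
additive Gaussian read noise.

Movies
------
Comets are born on each side of the midline by a homogeneous Poisson
process, uniform along the midline, and travel perpendicular to it at
constant speed; each comet is an isotropic Gaussian spot.  The per-side
birth rate is calibrated so that the expected number of comets crossing a
5-μm line at 3 μm offset within a 10-s window equals the ground-truth
``comet_emission``.  A point-source mode emits comets radially from a
centrosome for the 2-cell / E8 comparison.  Whole-frame intensity decays
exponentially with the bleach rate before noise is applied.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .datatypes import EmbryoAnnotation, GroundTruth, ImageStack, SceneParams, TimeLapse
from .geometry import Rect, Segment

APICAL_PLATEAU_UM = 1.0
CYTO_PLATEAU_UM = 2.5
CROSSING_OFFSET_UM = 3.0
CROSSING_LINE_UM = 5.0
CROSSING_WINDOW_S = 10.0


def profile_factor(d: np.ndarray, enrichment_ratio: float) -> np.ndarray:
    """Background-free radial profile g(d): plateau ``r`` apically, 1 in cytoplasm."""
    a = np.abs(np.asarray(d, dtype=float))
    ramp = (CYTO_PLATEAU_UM - a) / (CYTO_PLATEAU_UM - APICAL_PLATEAU_UM)
    g = 1.0 + (enrichment_ratio - 1.0) * np.clip(ramp, 0.0, 1.0)
    return g


def _pixel_grids(scene: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = scene.image_shape
    y = np.arange(rows)[:, None] * scene.pixel_size
    x = np.arange(cols)[None, :] * scene.pixel_size
    return x, y


def default_midline(scene: SceneParams) -> Segment:
    """Vertical midline through the field center, directed down the image."""
    xc = (scene.image_shape[1] - 1) / 2.0 * scene.pixel_size
    yc = (scene.image_shape[0] - 1) / 2.0 * scene.pixel_size
    half = scene.primordium_length / 2.0
    return Segment(xc, yc - half, xc, yc + half)


def default_annotation(scene: SceneParams) -> EmbryoAnnotation:
    """Place all measurement ROIs consistently with their invariants.

    Raises a geometry error when the boxes do not fit inside the plateau
    regions (for instance a primordium too narrow for the 10-μm gut box).
    """
    mid = default_midline(scene)
    xc = mid.x0
    yc = float(mid.midpoint[1])
    hw = scene.primordium_half_width
    if hw < 5.0:
        raise ValueError(
            "primordium_half_width must be >= 5 μm so the 10-μm gut box and the "
            "cytoplasmic box fit inside the primordium"
        )
    ylen = scene.primordium_length / 4.0
    gut_box = Rect(xc - 5.0, yc - ylen, xc + 5.0, yc + ylen)
    apical_box = Rect(xc - 1.0, yc - ylen, xc + 1.0, yc + ylen)
    cyto_box = Rect(xc + 2.5, yc - ylen, xc + 4.5, yc + ylen)
    # external box sits in the embryo-free margin along the left image edge
    m = scene.field_margin
    ex_x0 = 0.25 * scene.pixel_size
    external_box = Rect(ex_x0, yc - ylen, min(ex_x0 + 2.0, m - 0.1), yc + ylen)
    if external_box.x1 >= xc - hw:
        raise ValueError("external box does not fit in the embryo-free margin")
    bg_y = scene.field_height
    bg_rects = [
        Rect(ex_x0, 0.25 * scene.pixel_size, m - 0.1, 1.5),
        Rect(ex_x0, bg_y - 1.5, m - 0.1, bg_y - 0.25 * scene.pixel_size),
        Rect(scene.field_width - m + 0.1, 0.25 * scene.pixel_size,
             scene.field_width - 0.25 * scene.pixel_size, 1.5),
    ]
    ann = EmbryoAnnotation(
        midline=mid, gut_box=gut_box, external_box=external_box,
        apical_box=apical_box, cyto_box=cyto_box, bg_rects=bg_rects,
    )
    ann.validate()
    _check_outside_embryo(ann, scene)
    return ann


def _check_outside_embryo(ann: EmbryoAnnotation, scene: SceneParams) -> None:
    mid = ann.midline
    hw = scene.primordium_half_width
    for rect in [ann.external_box, *ann.bg_rects]:
        xs = np.array([rect.x0, rect.x1, rect.x0, rect.x1])
        ys = np.array([rect.y0, rect.y0, rect.y1, rect.y1])
        d = np.abs(mid.signed_distance(xs, ys))
        if (d < hw).any():
            raise ValueError(f"rectangle {rect} overlaps the embryo")


def gut_mask(scene: SceneParams, mid: Segment) -> np.ndarray:
    x, y = _pixel_grids(scene)
    d = mid.signed_distance(x, y)
    t = mid.axial_coordinate(x, y)
    return (np.abs(d) <= scene.primordium_half_width) & (t >= 0) & (t <= mid.length)


def _embryo_component(
    scene: SceneParams, mid: Segment, cyto: float, ratio: float, auto: float
) -> np.ndarray:
    """Noiseless in-focus embryo component: [gut] * (auto + cyto * g(d))."""
    x, y = _pixel_grids(scene)
    d = mid.signed_distance(x, y)
    g = profile_factor(d, ratio)
    return gut_mask(scene, mid) * (auto + cyto * g)


def apply_noise(mean: np.ndarray, noise, rng: np.random.Generator) -> np.ndarray:
    """Scaled-Poisson shot noise plus Gaussian read noise; zero params disable each."""
    out = np.asarray(mean, dtype=float)
    if noise.poisson_gain > 0:
        out = rng.poisson(noise.poisson_gain * np.clip(out, 0, None)) / noise.poisson_gain
    if noise.read_sd > 0:
        out = out + rng.normal(0.0, noise.read_sd, size=out.shape)
    return out


def _axial_weights(scene: SceneParams) -> np.ndarray:
    zc = (scene.n_z - 1) / 2.0
    z = (np.arange(scene.n_z) - zc) * scene.z_step
    return np.exp(-(z ** 2) / (2.0 * scene.z_sigma ** 2))


def generate_primordium_image(
    scene: SceneParams,
    truth: GroundTruth,
    seed: int,
    marker_scale: float = 1.0,
    haze_scale: float = 1.0,
) -> tuple[dict[str, ImageStack], EmbryoAnnotation, GroundTruth]:
    """Render a two-channel z-stack of one embryo with known ground truth.

    ``marker_scale`` multiplies the gut marker component (used by the
    depletion-cohort generator: 1 - δ for degraded embryos, 0 for no-GFP
    controls).  Haze originates in neighbouring, non-degraded tissues, so it
    is controlled separately by ``haze_scale`` (0 for no-GFP controls).
    Identical (scene, truth, seed) give bit-identical output.
    """
    ann = default_annotation(scene)
    rng = np.random.default_rng(seed)
    w = _axial_weights(scene)

    marker_embryo = marker_scale * _embryo_component(
        scene, ann.midline, truth.cyto_level, truth.enrichment_ratio, 0.0
    ) + gut_mask(scene, ann.midline) * truth.autofluo_level
    tub_embryo = _embryo_component(
        scene, ann.midline, truth.tub_cyto_level, truth.tub_enrichment, 0.0
    )

    stacks: dict[str, ImageStack] = {}
    for channel, embryo, haze in [
        ("marker", marker_embryo, haze_scale * truth.haze_level),
        ("tubulin", tub_embryo, 0.0),
    ]:
        planes = np.stack([
            apply_noise(truth.slide_bg + haze + w[z] * embryo, truth.noise, rng)
            for z in range(scene.n_z)
        ])
        stacks[channel] = ImageStack(planes, scene.pixel_size, scene.z_step, channel)
    return stacks, ann, truth


def generate_depletion_cohort(
    scene: SceneParams,
    truth: GroundTruth,
    n_minus: int,
    n_plus: int,
    seed: int,
    n_controls: int = 5,
) -> tuple[list, list, list, GroundTruth]:
    """Sibling cohorts for the percent-depletion assay.

    gut(−) embryos carry the degradation array, so their gut marker component
    (cytoplasmic level and apical peak together) is scaled by (1 − δ);
    gut(+) siblings are unscaled; no-GFP controls have no marker or haze but
    retain gut autofluorescence.  Haze, autofluorescence and slide background
    are identically distributed across the sibling cohorts.  Embryo-to-embryo
    expression variability multiplies the marker level by a factor with CV
    ``truth.embryo_cv``.
    """
    if n_minus < 1 or n_plus < 1:
        raise ValueError("need at least one embryo per cohort")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_minus + n_plus + n_controls)
    var_rng = np.random.default_rng(ss.spawn(1)[0])

    def make(scale: float, haze: float, sub_seed, vary: bool):
        factor = max(0.1, 1.0 + truth.embryo_cv * var_rng.standard_normal()) if vary else 1.0
        t = dataclasses.replace(truth, cyto_level=truth.cyto_level * factor)
        s = int(sub_seed.generate_state(1)[0] % (2 ** 31))
        stacks, ann, _ = generate_primordium_image(
            scene, t, s, marker_scale=scale, haze_scale=haze
        )
        return stacks, ann

    minus = [make(1.0 - truth.depletion_fraction, 1.0, child[i], True)
             for i in range(n_minus)]
    plus = [make(1.0, 1.0, child[n_minus + i], True) for i in range(n_plus)]
    controls = [make(0.0, 0.0, child[n_minus + n_plus + i], False)
                for i in range(n_controls)]
    return minus, plus, controls, truth


def crossing_lines(
    midline: Segment,
    offset: float = CROSSING_OFFSET_UM,
    line_length: float = CROSSING_LINE_UM,
) -> tuple[Segment, Segment]:
    """The two counting lines parallel to the midline at ±offset, centered axially."""
    u = midline.direction
    n = np.array([-u[1], u[0]])  # +n is the positive-signed-distance side
    mid = midline.midpoint
    half = line_length / 2.0
    out = []
    for s in (-1.0, +1.0):
        c = mid + s * offset * n
        out.append(Segment(
            float(c[0] - half * u[0]), float(c[1] - half * u[1]),
            float(c[0] + half * u[0]), float(c[1] + half * u[1]),
        ))
    return out[0], out[1]


def expected_crossing_rate_per_side(
    truth: GroundTruth,
    midline_length: float,
    offset: float = CROSSING_OFFSET_UM,
    line_length: float = CROSSING_LINE_UM,
    window: float = CROSSING_WINDOW_S,
) -> float:
    """Per-side birth rate (per second) so E[crossings per line per window] = λ.

    Births are uniform along the midline; only those within the lateral span
    of the counting line, early enough to travel ``offset`` before the window
    closes, cross it.  When comets are too slow to reach the line within the
    window (including the stationary case) no calibration is possible and
    the uncalibrated rate λ·L/(line·window) is used.
    """
    lam = truth.comet_emission
    span = min(line_length, midline_length)
    travel = offset / truth.comet_speed if truth.comet_speed > 0 else np.inf
    effective = window - travel if travel < window else window
    return lam * (midline_length / span) / effective


def generate_comet_movie(
    scene: SceneParams,
    truth: GroundTruth,
    duration: float,
    seed: int,
    source: str = "midline",
    point_center: tuple[float, float] | None = None,
    min_births: int = 0,
    max_attempts: int = 64,
) -> tuple[TimeLapse, EmbryoAnnotation, GroundTruth, pd.DataFrame]:
    """Render a comet time-lapse with a full birth event log.

    ``source='midline'`` emits comets on both sides of the midline moving
    perpendicular to it; ``source='point'`` emits radially from a centrosome
    (default: field center).  ``min_births`` re-draws the event set (new
    substream) until at least that many comets are born, mirroring the
    practice of re-imaging embryos with too few measurable comets.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if scene.frame_interval is None:
        raise ValueError("frame_interval is required for movies")
    ann = default_annotation(scene)
    mid = ann.midline
    ss = np.random.SeedSequence(seed)

    events = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng(ss.spawn(1)[0])
        cand = _draw_births(truth, mid, duration, rng, source)
        if len(cand) >= min_births:
            events = cand
            break
    if events is None:
        raise RuntimeError(f"could not draw >= {min_births} comets in {max_attempts} attempts")
    noise_rng = np.random.default_rng(ss.spawn(1)[0])

    # frames at t = 0, fi, ..., duration inclusive, so a counting window
    # equal to the movie duration sees crossings up to its endpoint
    n_frames = int(round(duration / scene.frame_interval)) + 1
    rows, cols = scene.image_shape
    ps = scene.pixel_size
    sigma_px = truth.comet_sigma / ps
    halfwin = max(3, int(np.ceil(4 * sigma_px)))
    u = mid.direction
    nvec = np.array([-u[1], u[0]])
    mpoint = mid.midpoint

    movie = np.empty((n_frames, rows, cols), dtype=float)
    bg = truth.slide_bg + truth.cyto_level
    for k in range(n_frames):
        t = k * scene.frame_interval
        frame = np.full((rows, cols), bg, dtype=float)
        for ev in events.itertuples():
            if t < ev.time_s:
                continue
            travel = truth.comet_speed * (t - ev.time_s)
            if ev.source == "midline":
                origin = np.array([mid.x0, mid.y0]) + ev.lateral_um * u
                base = ev.side_sign * nvec
                ca, sa = np.cos(np.deg2rad(ev.angle_deg)), np.sin(np.deg2rad(ev.angle_deg))
                direction = np.array([ca * base[0] - sa * base[1],
                                      sa * base[0] + ca * base[1]])
            else:
                origin = np.asarray(point_center if point_center is not None
                                    else [(cols - 1) / 2.0 * ps, (rows - 1) / 2.0 * ps])
                theta = np.deg2rad(ev.angle_deg)
                direction = np.array([np.cos(theta), np.sin(theta)])
            pos = origin + travel * direction
            cx, cy = pos / ps
            if not (-halfwin <= cx < cols + halfwin and -halfwin <= cy < rows + halfwin):
                continue
            r0 = max(0, int(np.floor(cy)) - halfwin)
            r1 = min(rows, int(np.ceil(cy)) + halfwin + 1)
            c0 = max(0, int(np.floor(cx)) - halfwin)
            c1 = min(cols, int(np.ceil(cx)) + halfwin + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            yy = np.arange(r0, r1)[:, None] - cy
            xx = np.arange(c0, c1)[None, :] - cx
            frame[r0:r1, c0:c1] += truth.comet_amplitude * np.exp(
                -(yy * yy + xx * xx) / (2.0 * sigma_px * sigma_px)
            )
        frame *= np.exp(-truth.bleach_rate * t)
        movie[k] = apply_noise(frame, truth.noise, noise_rng)

    lapse = TimeLapse(movie, ps, scene.frame_interval)
    log = events.drop(columns=["source"]).copy()
    return lapse, ann, truth, log


def draw_comet_events(
    scene: SceneParams, truth: GroundTruth, duration: float, seed: int,
    source: str = "midline",
) -> pd.DataFrame:
    """Draw a comet birth log without rendering frames (fast calibration checks)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    mid = default_midline(scene)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    return _draw_births(truth, mid, duration, rng, source)


def _draw_births(
    truth: GroundTruth, mid: Segment, duration: float,
    rng: np.random.Generator, source: str,
) -> pd.DataFrame:
    recs = []
    if source == "midline":
        rate = expected_crossing_rate_per_side(truth, mid.length)
        for side_sign, side in [(-1.0, "left"), (+1.0, "right")]:
            n = rng.poisson(rate * duration)
            times = np.sort(rng.uniform(0.0, duration, size=n))
            lateral = rng.uniform(0.0, mid.length, size=n)
            # microtubule tracks splay slightly about the outward normal
            angles = rng.normal(0.0, truth.comet_angle_sd, size=n)
            for t, lat, a in zip(times, lateral, angles):
                recs.append((t, side, side_sign, float(lat), truth.comet_speed,
                             float(a), source))
    elif source == "point":
        rate = truth.comet_emission / CROSSING_WINDOW_S
        n = rng.poisson(rate * duration)
        times = np.sort(rng.uniform(0.0, duration, size=n))
        angles = rng.uniform(0.0, 360.0, size=n)
        for t, a in zip(times, angles):
            side = "right" if np.cos(np.deg2rad(a)) >= 0 else "left"
            recs.append((t, side, 0.0, 0.0, truth.comet_speed, float(a), source))
    else:
        raise ValueError(f"unknown comet source {source!r}")
    return pd.DataFrame(
        recs,
        columns=["time_s", "side", "side_sign", "lateral_um", "speed_um_s",
                 "angle_deg", "source"],
    )


def generate_foci_image(
    scene: SceneParams,
    truth: GroundTruth,
    seed: int,
    spot_sigma: float = 0.3,
    spot_amplitude: float = 300.0,
    min_separation: float = 1.0,
    kind: str = "foci",
    planted_centers: list[tuple[float, float]] | None = None,
) -> tuple[ImageStack, EmbryoAnnotation]:
    """Plant ``k`` Gaussian spots (foci or nuclei) on the gut background.

    Foci centers are drawn uniformly inside the primordium with rejection
    sampling enforcing ``min_separation``, unless ``planted_centers`` plants
    them deliberately (e.g. closer than the separation limit to test the
    merge rule).  Nuclei (``kind='nuclei'``) are laid out in the two tiers
    of the E16 intestine: two rows flanking the midline, evenly spaced
    along it with slight positional jitter.  Centers are recorded in the
    annotation as ground truth.
    """
    ann = default_annotation(scene)
    rng = np.random.default_rng(seed)
    k = truth.nucleus_count if kind == "nuclei" else truth.foci_count
    mid = ann.midline

    if planted_centers is not None:
        centers = [tuple(map(float, c)) for c in planted_centers]
    elif kind == "nuclei":
        u = mid.direction
        nvec = np.array([-u[1], u[0]])
        p0 = np.array([mid.x0, mid.y0])
        centers = []
        per_row = (k + 1) // 2, k // 2
        for row_sign, n_row in zip((-1.0, 1.0), per_row):
            if n_row == 0:
                continue
            axial = (np.arange(n_row) + 0.5) / n_row * mid.length
            axial = axial + rng.uniform(-0.2, 0.2, size=n_row)
            d_off = row_sign * scene.primordium_half_width * 0.4
            for a in axial:
                p = p0 + a * u + (d_off + rng.uniform(-0.15, 0.15)) * nvec
                centers.append((float(p[0]), float(p[1])))
    else:
        centers = []
        guard = 0
        pad = 3.0 * spot_sigma
        while len(centers) < k:
            guard += 1
            if guard > 20000:
                raise RuntimeError("could not place spots with the requested separation")
            t = rng.uniform(pad, mid.length - pad)
            d = rng.uniform(-scene.primordium_half_width + pad,
                            scene.primordium_half_width - pad)
            u = mid.direction
            n = np.array([-u[1], u[0]])
            p = np.array([mid.x0, mid.y0]) + t * u + d * n
            if all(np.hypot(p[0] - c[0], p[1] - c[1]) >= min_separation for c in centers):
                centers.append((float(p[0]), float(p[1])))

    x, yy = _pixel_grids(scene)
    mean = np.full(scene.image_shape, truth.slide_bg, dtype=float)
    mean += gut_mask(scene, mid) * (truth.cyto_level + truth.autofluo_level)
    for (cx, cy) in centers:
        mean += spot_amplitude * np.exp(
            -((x - cx) ** 2 + (yy - cy) ** 2) / (2.0 * spot_sigma ** 2)
        )
    img = apply_noise(mean, truth.noise, rng)[None, :, :]
    stack = ImageStack(img, scene.pixel_size, scene.z_step, "marker")
    if kind == "nuclei":
        ann.nucleus_centers = centers
    else:
        ann.foci_centers = centers
    return stack, ann
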