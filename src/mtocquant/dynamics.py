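"""Comet kinetics: crossing counts, kymographs, and streak-slope speeds.

Comet counting follows the two-line rule: a 5-μm line is laid 3 μm from the
midline on each side and a comet is counted when its detected trajectory
crosses the line within a 10-s window (once per comet per line).  Speeds
come from kymographs: intensity is sampled along a path with a 5-pixel
width, a moving comet appears as a tilted streak, and the streak slope in
kymograph units converts to μm/s via the pixel size and frame interval.
Kymograph paths are placed automatically along each detected trajectory's
principal axis — the automated analogue of dragging the measurement line
along a comet's visible path.

Per-embryo rules: an embryo's mean speed requires at least two measured
comets; intestinal (E16) embryos falling short are flagged for reanalysis
while two-cell embryos are excluded outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import TimeLapse
from .geometry import Rect, Segment, clip_segment_to_rect
from .static import count_foci

log = logging.getLogger(__name__)

CROSSING_OFFSET_UM = 3.0
CROSSING_LINE_UM = 5.0
CROSSING_WINDOW_S = 10.0


@dataclass
class Trajectory:
    """One linked comet track: frame indices and positions in μm (x, y)."""

    frames: np.ndarray
    pos_um: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class Kymograph:
    """Distance-along-path × time intensity map (rows = frames)."""

    data: np.ndarray
    path: Segment
    width_px: int
    frame_interval: float
    pixel_size: float

    def __post_init__(self) -> None:
        if self.width_px % 2 != 1:
            raise ValueError("kymograph width must be odd")


@dataclass
class EmbryoSpeed:
    """Per-embryo mean comet speed with the >= 2-comet rule applied."""

    mean_speed: float | None
    status: str  # ok | insufficient | excluded
    speeds: list[float] = field(default_factory=list)


def detect_comets(
    frame: np.ndarray,
    pixel_size: float,
    sigma: float = 0.15,
    k_sd: float = 5.0,
    min_separation: float = 0.25,
) -> np.ndarray:
    """Comet candidates in one frame as (row, col) pixel coordinates."""
    _, peaks = count_foci(frame, pixel_size, min_separation, sigma, k_sd)
    return peaks


def link_trajectories(
    detections: list[np.ndarray],
    pixel_size: float,
    max_step_um: float,
    max_gap: int = 1,
    min_length: int = 2,
) -> list[Trajectory]:
    """Greedy nearest-neighbour frame-to-frame linking.

    Each active track is matched to the nearest unclaimed detection within
    ``max_step_um`` per elapsed frame (tracks may skip ``max_gap`` frames).
    Matches are assigned in ascending distance order, one detection per
    track.
    """
    active: list[dict] = []
    done: list[dict] = []
    for k, det in enumerate(detections):
        det = np.asarray(det, dtype=float).reshape(-1, 2)
        pos = det[:, ::-1] * pixel_size  # (x, y) μm
        still_active = [tr for tr in active if k - tr["frames"][-1] <= max_gap + 1]
        done.extend(tr for tr in active if k - tr["frames"][-1] > max_gap + 1)
        active = still_active

        pairs = []
        for ti, tr in enumerate(active):
            gap = k - tr["frames"][-1]
            lim = max_step_um * gap
            dist = np.linalg.norm(pos - tr["pos"][-1], axis=1)
            for di in np.nonzero(dist <= lim)[0]:
                pairs.append((dist[di], ti, int(di)))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            active[ti]["frames"].append(k)
            active[ti]["pos"].append(pos[di])
        for di in range(len(pos)):
            if di not in used_d:
                active.append({"frames": [k], "pos": [pos[di]]})
    done.extend(active)
    return [
        Trajectory(np.asarray(tr["frames"]), np.asarray(tr["pos"]))
        for tr in done
        if len(tr["frames"]) >= min_length
    ]


def track_movie(
    movie: TimeLapse,
    sigma: float = 0.15,
    k_sd: float = 5.0,
    v_max: float = 1.5,
    min_length: int = 2,
) -> list[Trajectory]:
    """Detect comets in every frame and link them into trajectories.

    The linking step limit is 3·``v_max``·frame_interval, with ``v_max`` an
    upper bound on plausible comet speed (μm/s).
    """
    detections = [detect_comets(f, movie.pixel_size, sigma, k_sd) for f in movie.data]
    max_step = 3.0 * v_max * movie.frame_interval
    return link_trajectories(detections, movie.pixel_size, max_step, min_length=min_length)


def count_crossings(
    movie: TimeLapse,
    midline: Segment,
    offset: float = CROSSING_OFFSET_UM,
    line_length: float = CROSSING_LINE_UM,
    window: float = CROSSING_WINDOW_S,
    trajectories: list[Trajectory] | None = None,
    resolve_doubles: bool = True,
    **track_kw,
) -> tuple[int, int, int]:
    """Count comets crossing the two offset lines within the window.

    A crossing is a trajectory whose |signed distance| from the midline
    passes from < ``offset`` to >= ``offset`` while its position along the
    midline stays within the lateral span of the 5-μm line; each comet
    counts at most once per line.  With ``resolve_doubles`` a crossing spot
    whose brightness is a clear multiple of the single-comet brightness is
    counted as that many comets — the counterpart of a human counter
    scoring an unresolved double-bright comet as two.  Returns
    (left, right, total).
    """
    if window > movie.duration + 1e-9:
        raise ValueError("counting window exceeds the movie duration")
    if trajectories is None:
        trajectories = track_movie(movie, **track_kw)
    half_span = line_length / 2.0
    t_mid = midline.length / 2.0
    brightness, unit = (_spot_brightness(movie, trajectories)
                        if resolve_doubles else (None, 0.0))
    counts = {"left": 0, "right": 0}
    for ti, tr in enumerate(trajectories):
        times = tr.frames * movie.frame_interval
        d = midline.signed_distance(tr.pos_um[:, 0], tr.pos_um[:, 1])
        a = midline.axial_coordinate(tr.pos_um[:, 0], tr.pos_um[:, 1])
        for side, sign in (("left", -1.0), ("right", 1.0)):
            s = sign * d
            crossed = (s[:-1] < offset) & (s[1:] >= offset)
            idx = np.nonzero(crossed)[0]
            for i in idx:
                if times[i + 1] <= window and abs(a[i + 1] - t_mid) <= half_span:
                    mult = 1
                    if brightness is not None and unit > 0:
                        # brightness around the crossing frames: an
                        # unresolved pair crossing as one spot is ~2 units
                        lo, hi = max(0, i - 3), min(tr.n_frames, i + 5)
                        local = float(np.median(brightness[ti][lo:hi]))
                        mult = int(np.clip(round(local / unit), 1, 3))
                    counts[side] += mult
                    break
    return counts["left"], counts["right"], counts["left"] + counts["right"]


def _spot_brightness(
    movie: TimeLapse, trajectories: list[Trajectory]
) -> tuple[list[np.ndarray], float]:
    """Per-frame spot brightness of every trajectory and the single-comet unit.

    Brightness is the intensity above the frame median at the detected
    position; the median over all trajectories' per-trajectory medians
    serves as the one-comet unit, since most tracked spots are single
    comets.  An unresolved pair rides as one spot of roughly two units.
    """
    rows, cols = movie.data.shape[1:]
    frame_bg = np.median(movie.data, axis=(1, 2))
    series = []
    for tr in trajectories:
        rc = np.clip(np.round(tr.pos_um[:, ::-1] / movie.pixel_size).astype(int),
                     0, [rows - 1, cols - 1])
        series.append(movie.data[tr.frames, rc[:, 0], rc[:, 1]] - frame_bg[tr.frames])
    unit = float(np.median([np.median(s) for s in series])) if series else 0.0
    return series, unit


def make_kymograph(movie: TimeLapse, path: Segment, width_px: int = 5) -> Kymograph:
    """Sample intensity along ``path`` at unit-pixel steps, averaged across
    ``width_px`` perpendicular offsets, bilinearly interpolated per frame."""
    if width_px % 2 != 1 or width_px < 1:
        raise ValueError("width must be odd and positive")
    ps = movie.pixel_size
    rows, cols = movie.data.shape[1:]
    n_steps = int(np.floor(path.length / ps)) + 1
    if n_steps < 2:
        raise ValueError("path is shorter than one pixel")
    u = path.direction
    n = np.array([-u[1], u[0]])
    s = np.arange(n_steps) * ps
    offs = (np.arange(width_px) - width_px // 2) * ps
    # sample positions in μm: (n_steps, width)
    px = path.x0 + s[:, None] * u[0] + offs[None, :] * n[0]
    py = path.y0 + s[:, None] * u[1] + offs[None, :] * n[1]
    rr = py / ps
    cc = px / ps
    if rr.min() < -0.5 or cc.min() < -0.5 or rr.max() > rows - 0.5 or cc.max() > cols - 0.5:
        raise ValueError("kymograph path (with its width) exits the field")
    coords = np.stack([rr.ravel(), cc.ravel()])
    out = np.empty((movie.n_frames, n_steps), dtype=float)
    for k in range(movie.n_frames):
        vals = ndimage.map_coordinates(movie.data[k], coords, order=1, mode="nearest")
        out[k] = vals.reshape(n_steps, width_px).mean(axis=1)
    return Kymograph(out, path, width_px, movie.frame_interval, ps)


def estimate_speeds(
    kymo: Kymograph,
    min_streak_frames: int = 5,
    k_sd: float = 3.0,
    r2_min: float = 0.8,
) -> pd.DataFrame:
    """Extract streaks from a kymograph and fit each slope by least squares.

    The kymograph is thresholded at a robust background level, 8-connected
    components spanning at least ``min_streak_frames`` time rows are kept,
    each row's intensity-weighted centroid gives distance vs time, and an
    OLS fit yields the slope; |slope| converts to μm/s.  Fits with R² below
    ``r2_min`` are discarded.  A perfectly vertical streak (stationary spot)
    has zero distance variance and is reported as speed 0 with R² = 1.
    Columns: speed_um_s, slope_sign, r2, n_frames, t_start, t_end.
    """
    if kymo.data.shape[0] < min_streak_frames:
        raise ValueError("kymograph has fewer rows than min_streak_frames")
    img = kymo.data
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    thr = med + k_sd * 1.4826 * mad + 1e-6 * max(1.0, abs(med))
    mask = img > thr
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    recs = []
    w = np.clip(img - thr, 0, None)
    for lab in range(1, n_lab + 1):
        comp = labels == lab
        trows = np.nonzero(comp.any(axis=1))[0]
        if len(trows) < min_streak_frames:
            continue
        cols_idx = np.arange(img.shape[1])
        cent = np.array([
            (w[t][comp[t]] * cols_idx[comp[t]]).sum() / w[t][comp[t]].sum()
            if w[t][comp[t]].sum() > 0 else cols_idx[comp[t]].mean()
            for t in trows
        ])
        slope, intercept = np.polyfit(trows, cent, 1)
        pred = slope * trows + intercept
        ss_res = float(((cent - pred) ** 2).sum())
        ss_tot = float(((cent - cent.mean()) ** 2).sum())
        if ss_tot <= 1e-12:
            r2, slope = 1.0, 0.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        if r2 < r2_min:
            continue
        speed = abs(slope) * kymo.pixel_size / kymo.frame_interval
        recs.append({
            "speed_um_s": speed,
            "slope_sign": float(np.sign(slope)),
            "r2": r2,
            "n_frames": len(trows),
            "t_start": int(trows[0]),
            "t_end": int(trows[-1]),
        })
    return pd.DataFrame(
        recs, columns=["speed_um_s", "slope_sign", "r2", "n_frames", "t_start", "t_end"]
    )


def _trajectory_path(
    tr: Trajectory,
    movie: TimeLapse,
    width_px: int,
    pad_um: float = 1.0,
    usable: np.ndarray | None = None,
) -> Segment | None:
    """Kymograph path along a trajectory's principal axis, clipped to the field.

    When a usability mask is given (rows not contaminated by neighbouring
    comets), the direction is fitted from the clean positions only.
    """
    pos = tr.pos_um
    if usable is not None and usable.sum() >= 3:
        pos = pos[usable]
    centroid = pos.mean(axis=0)
    centered = pos - centroid
    if np.abs(centered).max() < 1.5 * movie.pixel_size:
        u = np.array([1.0, 0.0])  # stationary spot: direction is arbitrary
    else:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        u = vt[0]
    proj = centered @ u
    lo, hi = proj.min() - pad_um, proj.max() + pad_um
    a = centroid + lo * u
    b = centroid + hi * u
    ps = movie.pixel_size
    rows, cols = movie.data.shape[1:]
    inset = (width_px // 2 + 2) * ps
    rect = Rect(inset, inset, (cols - 1) * ps - inset, (rows - 1) * ps - inset)
    try:
        seg = clip_segment_to_rect(
            Segment(float(a[0]), float(a[1]), float(b[0]), float(b[1])), rect
        )
    except ValueError:
        return None
    if seg.length < 3 * ps:
        return None
    return seg


def _guided_streak_fit(
    kymo: Kymograph,
    tr: Trajectory,
    min_streak_frames: int,
    window_px: int = 4,
    usable: np.ndarray | None = None,
) -> tuple[float, float, int, float, float] | None:
    """Fit the slope of the one streak a trajectory identifies.

    Movies of real embryos carry many simultaneous comets, so a kymograph
    along one comet's path is crossed by the streaks of others; measuring
    "the slope of one comet" means reading only the streak that belongs to
    the comet the line was drawn along.  For each frame of the trajectory
    the comet's projected position on the path seeds a ±``window_px``
    column window, the intensity-weighted centroid inside the window gives
    distance vs time, and OLS yields the slope.  Returns (slope_px_per_frame,
    r2, n_rows) or None when too few rows carry signal.
    """
    img = kymo.data
    med = float(np.median(img))
    ps = kymo.pixel_size
    u = kymo.path.direction
    proj = ((tr.pos_um[:, 0] - kymo.path.x0) * u[0]
            + (tr.pos_um[:, 1] - kymo.path.y0) * u[1]) / ps
    rows_used, cents, peaks = [], [], []
    n_cols = img.shape[1]
    if usable is None:
        usable = np.ones(tr.n_frames, dtype=bool)
    for frame, p, ok in zip(tr.frames, proj, usable):
        if not ok or not (0 <= frame < img.shape[0]):
            continue
        j0 = int(round(p)) - window_px
        j1 = int(round(p)) + window_px + 1
        if j0 < 0 or j1 > n_cols:
            continue  # truncated windows at the path ends bias the centroid
        w = np.clip(img[frame, j0:j1] - med, 0, None)
        if w.sum() <= 0:
            continue
        cents.append(float((w * np.arange(j0, j1)).sum() / w.sum()))
        peaks.append(float(w.max()))
        rows_used.append(frame)
    if len(rows_used) < min_streak_frames:
        return None
    t = np.asarray(rows_used, dtype=float)
    c = np.asarray(cents)
    # two robust passes: rows whose centroid was pulled off the streak by a
    # crossing comet show up as residual outliers and are dropped
    keep = np.ones(len(t), dtype=bool)
    for _ in range(2):
        slope, intercept = np.polyfit(t[keep], c[keep], 1)
        resid = c - (slope * t + intercept)
        new_keep = np.abs(resid) <= 1.5
        if new_keep.sum() < min_streak_frames or new_keep.all():
            break
        keep = new_keep
    t, c = t[keep], c[keep]
    if len(t) < min_streak_frames:
        return None
    slope, intercept = np.polyfit(t, c, 1)
    pred = slope * t + intercept
    ss_res = float(((c - pred) ** 2).sum())
    ss_tot = float(((c - c.mean()) ** 2).sum())
    ss_tt = float(((t - t.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot <= 1e-12 else 1.0 - ss_res / ss_tot
    if ss_tot <= 1e-12:
        slope = 0.0
    slope_se = np.sqrt(ss_res / max(len(t) - 2, 1) / ss_tt) if ss_tt > 0 else np.inf
    return float(slope), float(r2), len(t), float(slope_se), float(np.median(peaks))


def measure_comet_speeds(
    movie: TimeLapse,
    width_px: int = 5,
    min_traj_frames: int = 5,
    min_streak_frames: int = 5,
    r2_min: float = 0.8,
    speed_se_max: float = 0.03,
    exclusion: tuple | None = None,
    trajectories: list[Trajectory] | None = None,
    **track_kw,
) -> pd.DataFrame:
    """Per-comet speeds: one kymograph per detected trajectory.

    For every trajectory persisting at least ``min_traj_frames`` frames, a
    5-pixel-wide kymograph is built along its principal axis and the streak
    belonging to that comet is fitted by the guided per-row centroid rule
    (see :func:`_guided_streak_fit`).  Fits with R² below ``r2_min`` or a
    slope standard error above ``speed_se_max`` (μm/s) are discarded — the
    automated analogue of only measuring comets whose streak is clean enough
    to read.  ``exclusion`` optionally names the comet birth structure as
    ``(Segment, radius_um)`` or ``((x, y), radius_um)``: rows inside it are
    not read, because newborn comets pile up there before they can be
    resolved.  Returns one row per measured comet
    (comet_id, speed_um_s, r2, n_frames).
    """
    if trajectories is None:
        trajectories = track_movie(movie, min_length=min_traj_frames, **track_kw)
    # veto measurement rows where another comet sits inside (or near) the
    # centroid window.  Other comets' positions are interpolated across
    # linking gaps and extrapolated (constant velocity) beyond their track
    # ends: a track that starts only once a merged pair separates still has
    # a partner occupying the frames before its first detection
    clearance = (4 + 3.0) * movie.pixel_size
    extrapolate = 40  # frames
    models = []
    for tr in trajectories:
        if tr.n_frames >= 2:
            bx = np.polyfit(tr.frames, tr.pos_um[:, 0], 1)
            by = np.polyfit(tr.frames, tr.pos_um[:, 1], 1)
        else:
            bx = np.array([0.0, tr.pos_um[0, 0]])
            by = np.array([0.0, tr.pos_um[0, 1]])
        models.append((bx, by))
    recs = []
    for i, tr in enumerate(trajectories):
        if tr.n_frames < min_traj_frames:
            continue
        usable = np.ones(tr.n_frames, dtype=bool)
        f_i = tr.frames.astype(float)
        for jdx, other in enumerate(trajectories):
            if jdx == i:
                continue
            f0, f1 = other.frames[0], other.frames[-1]
            in_range = (f_i >= f0 - extrapolate) & (f_i <= f1 + extrapolate)
            if not in_range.any():
                continue
            ff = f_i[in_range]
            inside = (ff >= f0) & (ff <= f1)
            ox = np.empty_like(ff)
            oy = np.empty_like(ff)
            ox[inside] = np.interp(ff[inside], other.frames, other.pos_um[:, 0])
            oy[inside] = np.interp(ff[inside], other.frames, other.pos_um[:, 1])
            bx, by = models[jdx]
            ox[~inside] = np.polyval(bx, ff[~inside])
            oy[~inside] = np.polyval(by, ff[~inside])
            d = np.hypot(ox - tr.pos_um[in_range, 0], oy - tr.pos_um[in_range, 1])
            mask = np.nonzero(in_range)[0][d < clearance]
            usable[mask] = False
        if exclusion is not None:
            zone, radius = exclusion
            if isinstance(zone, Segment):
                dist = np.abs(zone.signed_distance(tr.pos_um[:, 0], tr.pos_um[:, 1]))
            else:
                dist = np.hypot(tr.pos_um[:, 0] - zone[0], tr.pos_um[:, 1] - zone[1])
            usable &= dist >= radius
        path = _trajectory_path(tr, movie, width_px, usable=usable)
        if path is None:
            continue
        kymo = make_kymograph(movie, path, width_px)
        fit = _guided_streak_fit(kymo, tr, min_streak_frames, usable=usable)
        if fit is None:
            continue
        slope, r2, n_rows, slope_se, peak = fit
        speed_se = slope_se * kymo.pixel_size / kymo.frame_interval
        if r2 < r2_min or speed_se > speed_se_max:
            continue
        recs.append({
            "comet_id": i,
            "speed_um_s": abs(slope) * kymo.pixel_size / kymo.frame_interval,
            "r2": r2,
            "n_frames": n_rows,
            "peak": peak,
        })
    df = pd.DataFrame(recs, columns=["comet_id", "speed_um_s", "r2", "n_frames", "peak"])
    if len(df) >= 4:
        # an unresolved pair of comets rides as one spot of roughly doubled
        # brightness; such streaks report the pair's mean velocity, not one
        # comet's, so they are not measured
        df = df[df["peak"] <= 1.6 * df["peak"].median()]
    return df.drop(columns=["peak"]).reset_index(drop=True)


def embryo_mean_speed(speeds: list[float], context: str = "E16") -> EmbryoSpeed:
    """Apply the >= 2-comet per-embryo rule.

    E16 embryos with fewer than two measured comets are flagged
    ``insufficient`` (the caller should supply more streaks or drop the
    embryo); two-cell embryos are ``excluded``.
    """
    if context not in ("E16", "two_cell"):
        raise ValueError("context must be 'E16' or 'two_cell'")
    speeds = [float(s) for s in speeds]
    if len(speeds) < 2:
        status = "excluded" if context == "two_cell" else "insufficient"
        return EmbryoSpeed(None, status, speeds)
    return EmbryoSpeed(float(np.mean(speeds)), "ok", speeds)


def genotype_summary(
    per_embryo: pd.DataFrame, total_comets_min: int = 30
) -> pd.DataFrame:
    """Per-genotype mean ± SD of embryo mean speeds and crossing counts.

    ``per_embryo`` needs columns genotype, mean_speed, crossings_total and
    n_comets.  Genotypes whose total analyzed comets fall below
    ``total_comets_min`` are flagged (and logged); a single-embryo genotype
    reports SD 0 with a flag.
    """
    rows = []
    for geno, grp in per_embryo.groupby("genotype", sort=True):
        n = len(grp)
        total = int(grp["n_comets"].sum())
        flag = []
        if total < total_comets_min:
            flag.append("few_comets")
            log.warning("genotype %s: only %d comets analyzed (< %d)",
                        geno, total, total_comets_min)
        if n < 2:
            flag.append("single_embryo")
        rows.append({
            "genotype": geno,
            "n_embryos": n,
            "total_comets": total,
            "speed_mean": float(grp["mean_speed"].mean()),
            "speed_sd": float(grp["mean_speed"].std(ddof=1)) if n > 1 else 0.0,
            "count_mean": float(grp["crossings_total"].mean()),
            "count_sd": float(grp["crossings_total"].std(ddof=1)) if n > 1 else 0.0,
            "flags": ";".join(flag),
        })
    return pd.DataFrame(rows)
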