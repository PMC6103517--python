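"""Comet tracking, crossing counts, kymographs and speed estimation."""

import numpy as np
import pandas as pd
import pytest

from mtocquant.datatypes import GroundTruth, NoiseParams, TimeLapse
from mtocquant.dynamics import (
    Kymograph,
    count_crossings,
    embryo_mean_speed,
    estimate_speeds,
    genotype_summary,
    make_kymograph,
    measure_comet_speeds,
    track_movie,
)
from mtocquant.geometry import Segment
from mtocquant.synthetic import generate_comet_movie
from tests.conftest import NOISELESS

PS, FI = 0.11, 0.1


def spot_movie(positions_um, shape=(96, 96), amp=150.0, bg=50.0, sigma=0.15):
    """Render a movie from explicit per-frame spot positions (x, y) in μm."""
    frames = []
    for pts in positions_um:
        f = np.full(shape, bg)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        for (x, y) in pts:
            f += amp * np.exp(-(((xx * PS - x) ** 2) + (yy * PS - y) ** 2)
                              / (2 * sigma ** 2))
        frames.append(f)
    return TimeLapse(np.asarray(frames), PS, FI)


class TestCrossings:
    def test_zero_emission_counts_zero(self, movie_scene):
        truth = GroundTruth(comet_emission=0.0, noise=NOISELESS)
        movie, ann, _, _ = generate_comet_movie(movie_scene, truth, 10.0, seed=0)
        assert count_crossings(movie, ann.midline) == (0, 0, 0)

    def test_single_rightward_comet(self):
        # comet starts on the midline at x=5 and moves right at 0.5 um/s;
        # the midline is directed so that +x is its right-hand side
        mid = Segment(5.0, 9.0, 5.0, 1.0)
        n = 100
        pos = [[(5.0 + 0.5 * k * FI, 5.0)] for k in range(n)]
        movie = spot_movie(pos)
        assert count_crossings(movie, mid) == (0, 1, 1)

    def test_noiseless_counts_match_event_log_oracle(self, movie_scene):
        # noiseless movies whose comets are all optically resolvable and
        # whose crossings do not graze the counting-line boundary: the
        # trajectory-based count equals an independent frame-by-frame
        # simulation of the true comet positions, exactly
        truth = GroundTruth(comet_speed=0.558, comet_emission=0.8, noise=NOISELESS)
        checked = 0
        for seed in range(60):
            if checked >= 4:
                break
            movie, ann, _, log = generate_comet_movie(movie_scene, truth, 10.0, seed)
            if not self.scene_is_unambiguous(log, ann.midline):
                continue
            checked += 1
            _, _, total = count_crossings(movie, ann.midline)
            oracle = self.event_log_oracle(log, ann.midline, movie.n_frames)
            assert total == oracle, f"seed {seed}"
        assert checked == 4

    @staticmethod
    def scene_is_unambiguous(log, midline, resolution=0.6, margin=0.15,
                             offset=3.0, half_span=2.5, window=10.0):
        """True when no two same-side comets can merge into one spot and no
        crossing falls within ``margin`` of a counting boundary."""
        t_mid = midline.length / 2.0
        for ev in log.itertuples():
            a = np.deg2rad(ev.angle_deg)
            t_cross = ev.time_s + offset / (ev.speed_um_s * np.cos(a))
            ax = ev.lateral_um - ev.side_sign * offset * np.tan(a)
            if abs(abs(ax - t_mid) - half_span) < margin:
                return False
            if abs(t_cross - window) < margin:
                return False
        for side in ("left", "right"):
            sub = log[log.side == side]
            lat = sub.lateral_um.to_numpy()
            t = sub.time_s.to_numpy()
            v = sub.speed_um_s.to_numpy()
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    if (abs(lat[i] - lat[j]) < resolution
                            and abs(v[i] * (t[i] - t[j])) < resolution):
                        return False
        return True

    @staticmethod
    def event_log_oracle(log, midline, n_frames, offset=3.0, half_span=2.5,
                         window=10.0, fi=FI):
        u = midline.direction
        t_mid = midline.length / 2.0
        count = 0
        for ev in log.itertuples():
            a = np.deg2rad(ev.angle_deg)
            d_speed = ev.speed_um_s * np.cos(a)
            ax_speed = -ev.side_sign * ev.speed_um_s * np.sin(a)
            prev_d = 0.0
            for k in range(n_frames):
                t = k * fi - ev.time_s
                if t < 0:
                    continue
                d = d_speed * t
                axial = ev.lateral_um + ax_speed * t
                if prev_d < offset <= d:
                    if k * fi <= window and abs(axial - t_mid) <= half_span:
                        count += 1
                    break
                prev_d = d
        return count

    def test_window_longer_than_movie_rejected(self, movie_scene):
        truth = GroundTruth(comet_emission=0.0, noise=NOISELESS)
        movie, ann, _, _ = generate_comet_movie(movie_scene, truth, 5.0, seed=0)
        with pytest.raises(ValueError, match="window"):
            count_crossings(movie, ann.midline, window=10.0)


class TestKymograph:
    def test_uniform_movie_gives_uniform_kymograph(self):
        movie = TimeLapse(np.full((10, 64, 64), 3.0), PS, FI)
        kymo = make_kymograph(movie, Segment(1.0, 3.0, 5.0, 3.0))
        assert np.allclose(kymo.data, 3.0)

    def test_stationary_spot_vertical_streak(self):
        movie = spot_movie([[(3.0, 3.0)]] * 20)
        kymo = make_kymograph(movie, Segment(1.0, 3.0, 5.0, 3.0))
        cols = np.argmax(kymo.data, axis=1)
        assert np.all(cols == cols[0])
        speeds = estimate_speeds(kymo)
        assert len(speeds) == 1
        assert speeds["speed_um_s"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_moving_comet_slope_matches_event_log(self, movie_scene):
        v = 0.558
        truth = GroundTruth(comet_speed=v, comet_emission=0.3, noise=NOISELESS)
        movie, ann, _, log = generate_comet_movie(movie_scene, truth, 10.0, seed=1,
                                                  min_births=1)
        ev = log.iloc[0]
        u = ann.midline.direction
        base = np.array([-u[1], u[0]]) * ev.side_sign
        a = np.deg2rad(ev.angle_deg)
        nvec = np.array([np.cos(a) * base[0] - np.sin(a) * base[1],
                         np.sin(a) * base[0] + np.cos(a) * base[1]])
        origin = np.array([ann.midline.x0, ann.midline.y0]) + ev.lateral_um * u
        path = Segment(origin[0], origin[1],
                       origin[0] + 6.0 * nvec[0], origin[1] + 6.0 * nvec[1])
        kymo = make_kymograph(movie, path)
        speeds = estimate_speeds(kymo)
        assert len(speeds) >= 1
        # slope in kymograph units is v * frame_interval / pixel_size
        slope_px = speeds["speed_um_s"].iloc[0] * FI / PS
        assert slope_px == pytest.approx(v * FI / PS, rel=0.05)

    def test_path_exiting_field_rejected(self):
        movie = TimeLapse(np.zeros((5, 32, 32)), PS, FI)
        with pytest.raises(ValueError, match="exits the field"):
            make_kymograph(movie, Segment(0.0, 1.0, 10.0, 1.0))

    def test_even_width_rejected(self):
        movie = TimeLapse(np.zeros((5, 64, 64)), PS, FI)
        with pytest.raises(ValueError, match="odd"):
            make_kymograph(movie, Segment(1.0, 3.0, 4.0, 3.0), width_px=4)

    def test_empty_kymograph_yields_no_streaks(self):
        kymo = Kymograph(np.zeros((20, 40)), Segment(0, 0, 4.0, 0), 5, FI, PS)
        assert estimate_speeds(kymo).empty


class TestSpeedMeasurement:
    @pytest.mark.parametrize("v", [0.2, 0.5, 0.8, 1.2])
    def test_noiseless_single_comet_within_5_percent(self, movie_scene, v):
        truth = GroundTruth(comet_speed=v, comet_emission=0.3, noise=NOISELESS)
        errs = []
        for seed in range(3):
            movie, _, _, _ = generate_comet_movie(movie_scene, truth, 10.0, seed,
                                                  min_births=1)
            df = measure_comet_speeds(movie)
            errs.extend(abs(df["speed_um_s"] - v) / v)
        assert errs and max(errs) < 0.05

    def test_intensity_scaling_invariance(self, movie_scene):
        truth = GroundTruth(comet_speed=0.6, comet_emission=0.5, noise=NOISELESS)
        movie, _, _, _ = generate_comet_movie(movie_scene, truth, 10.0, seed=4,
                                              min_births=1)
        df1 = measure_comet_speeds(movie)
        scaled = TimeLapse(movie.data * 7.5, movie.pixel_size, movie.frame_interval)
        df2 = measure_comet_speeds(scaled)
        assert np.allclose(df1["speed_um_s"], df2["speed_um_s"], rtol=1e-9)


class TestEmbryoRules:
    def test_mean_of_two(self):
        res = embryo_mean_speed([0.5, 0.7])
        assert res.status == "ok"
        assert res.mean_speed == pytest.approx(0.6)

    def test_two_cell_single_comet_excluded(self):
        assert embryo_mean_speed([0.9], context="two_cell").status == "excluded"

    def test_e16_single_comet_flagged_insufficient(self):
        assert embryo_mean_speed([0.9], context="E16").status == "insufficient"

    def test_empty_is_insufficient(self):
        assert embryo_mean_speed([]).status == "insufficient"


class TestGenotypeSummary:
    def test_single_embryo_flagged_with_zero_sd(self):
        df = pd.DataFrame([{"genotype": "control", "mean_speed": 0.56,
                            "crossings_total": 11, "n_comets": 40}])
        out = genotype_summary(df)
        assert out["speed_sd"].iloc[0] == 0.0
        assert "single_embryo" in out["flags"].iloc[0]

    def test_low_comet_total_warns(self):
        df = pd.DataFrame([
            {"genotype": "g", "mean_speed": 0.6, "crossings_total": 5, "n_comets": 10},
            {"genotype": "g", "mean_speed": 0.7, "crossings_total": 6, "n_comets": 12},
        ])
        out = genotype_summary(df, total_comets_min=30)
        assert "few_comets" in out["flags"].iloc[0]

    def test_welch_separates_genotypes_at_printed_speeds(self, rng):
        # power check: embryo means at 0.56 vs 0.72 (SD ~0.05), n=10 each
        from mtocquant.stats import welch_t_samples

        rejections = 0
        for _ in range(50):
            a = rng.normal(0.56, 0.05, size=10)
            b = rng.normal(0.72, 0.05, size=10)
            if welch_t_samples(a, b).p < 0.01:
                rejections += 1
        assert rejections >= 48
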