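"""The generator's contract: noiseless means, determinism, calibration."""

import dataclasses

import numpy as np
import pytest

from mtocquant.datatypes import GroundTruth, NoiseParams, SceneParams
from mtocquant.geometry import rect_mean
from mtocquant.synthetic import (
    default_annotation,
    draw_comet_events,
    generate_comet_movie,
    generate_depletion_cohort,
    generate_foci_image,
    generate_primordium_image,
    profile_factor,
    gut_mask,
)
from tests.conftest import NOISELESS


class TestPrimordiumImage:
    def test_flat_marker_when_ratio_is_one(self, still_scene):
        truth = GroundTruth(enrichment_ratio=1.0, slide_bg=0.0, noise=NOISELESS,
                            embryo_cv=0.0)
        stacks, ann, _ = generate_primordium_image(still_scene, truth, seed=0)
        img = stacks["marker"].data[still_scene.n_z // 2]
        gut = gut_mask(still_scene, ann.midline)
        assert np.ptp(img[gut]) == pytest.approx(0.0, abs=1e-9)

    def test_box_means_by_pixel_enumeration(self, still_scene, clean_truth):
        # r=3, C=100, zero backgrounds: apical box mean 300, cyto box mean 100
        stacks, ann, _ = generate_primordium_image(still_scene, clean_truth, seed=0)
        central = stacks["marker"].data[still_scene.n_z // 2]
        ps = still_scene.pixel_size
        apical = rect_mean(central, ann.apical_box, ps)
        cyto = rect_mean(central, ann.cyto_box, ps)
        assert apical == pytest.approx(300.0, abs=1e-9)
        assert cyto == pytest.approx(100.0, abs=1e-9)

    def test_noiseless_mean_formula_per_pixel(self, still_scene):
        truth = GroundTruth(enrichment_ratio=2.0, cyto_level=50.0, slide_bg=7.0,
                            haze_level=13.0, autofluo_level=4.0, noise=NOISELESS)
        stacks, ann, _ = generate_primordium_image(still_scene, truth, seed=0)
        central = stacks["marker"].data[still_scene.n_z // 2]
        ps = still_scene.pixel_size
        mid = ann.midline
        rs = np.random.default_rng(0).integers(0, 256, size=(60, 2))
        for r, c in rs:
            x, y = c * ps, r * ps
            d = float(mid.signed_distance(np.array([x]), np.array([y]))[0])
            t = float(mid.axial_coordinate(np.array([x]), np.array([y]))[0])
            in_gut = abs(d) <= still_scene.primordium_half_width and 0 <= t <= mid.length
            expect = 7.0 + 13.0
            if in_gut:
                expect += 4.0 + 50.0 * float(profile_factor(np.array([d]), 2.0)[0])
            assert central[r, c] == pytest.approx(expect, abs=1e-9)

    def test_determinism_bit_identical(self, still_scene):
        truth = GroundTruth()
        a, _, _ = generate_primordium_image(still_scene, truth, seed=7)
        b, _, _ = generate_primordium_image(still_scene, truth, seed=7)
        assert np.array_equal(a["marker"].data, b["marker"].data)
        assert np.array_equal(a["tubulin"].data, b["tubulin"].data)

    def test_scaling_cyto_level_scales_gut_signal(self, still_scene, clean_truth):
        s = 2.5
        scaled = dataclasses.replace(clean_truth, cyto_level=clean_truth.cyto_level * s)
        a, ann, _ = generate_primordium_image(still_scene, clean_truth, seed=0)
        b, _, _ = generate_primordium_image(still_scene, scaled, seed=0)
        gut = gut_mask(still_scene, ann.midline)
        za = a["marker"].data[:, gut]
        zb = b["marker"].data[:, gut]
        assert np.allclose(zb, s * za, rtol=1e-12)

    def test_narrow_primordium_rejected(self):
        with pytest.raises(ValueError, match="10-μm gut box"):
            default_annotation(SceneParams(primordium_half_width=4.0,
                                           image_shape=(256, 256)))

    def test_annotation_invariants(self, still_scene):
        ann = default_annotation(still_scene)
        ann.validate()
        assert ann.apical_box.width == pytest.approx(2.0)
        assert ann.cyto_box.width == pytest.approx(2.0)
        assert ann.gut_box.width == pytest.approx(10.0)
        # external box inside the embryo-free margin strip
        assert ann.external_box.x1 <= still_scene.field_margin


class TestDepletionCohort:
    def test_full_depletion_leaves_haze_and_autofluo_only(self, still_scene):
        truth = GroundTruth(depletion_fraction=1.0, slide_bg=5.0, haze_level=11.0,
                            autofluo_level=3.0, embryo_cv=0.0, noise=NOISELESS)
        minus, plus, controls, _ = generate_depletion_cohort(
            still_scene, truth, 1, 1, seed=0, n_controls=1
        )
        stacks, ann = minus[0]
        central = stacks["marker"].data[still_scene.n_z // 2]
        gut = gut_mask(still_scene, ann.midline)
        assert np.allclose(central[gut], 5.0 + 11.0 + 3.0, atol=1e-9)

    def test_zero_depletion_cohorts_identically_distributed(self, still_scene):
        truth = GroundTruth(depletion_fraction=0.0, embryo_cv=0.0, noise=NOISELESS)
        minus, plus, _, _ = generate_depletion_cohort(still_scene, truth, 1, 1, seed=0)
        assert np.array_equal(minus[0][0]["marker"].data, plus[0][0]["marker"].data)

    def test_invalid_depletion_fraction_rejected(self):
        with pytest.raises(ValueError, match="depletion_fraction"):
            GroundTruth(depletion_fraction=1.5)


class TestCometMovie:
    def test_zero_emission_background_only(self, movie_scene):
        truth = GroundTruth(comet_emission=0.0, noise=NOISELESS)
        movie, _, _, log = generate_comet_movie(movie_scene, truth, 10.0, seed=0)
        assert len(log) == 0
        assert np.ptp(movie.data) == pytest.approx(0.0, abs=1e-9)

    def test_determinism(self, movie_scene):
        truth = GroundTruth(comet_emission=3.0)
        a, _, _, la = generate_comet_movie(movie_scene, truth, 5.0, seed=11)
        b, _, _, lb = generate_comet_movie(movie_scene, truth, 5.0, seed=11)
        assert np.array_equal(a.data, b.data)
        assert la.equals(lb)

    def test_negative_duration_rejected(self, movie_scene):
        with pytest.raises(ValueError, match="duration"):
            generate_comet_movie(movie_scene, GroundTruth(), -1.0, seed=0)

    def test_bleach_decay_applied(self, movie_scene):
        truth = GroundTruth(comet_emission=0.0, bleach_rate=0.1, noise=NOISELESS)
        movie, _, _, _ = generate_comet_movie(movie_scene, truth, 5.0, seed=0)
        means = movie.data.mean(axis=(1, 2))
        t = np.arange(movie.n_frames) * movie_scene.frame_interval
        assert np.allclose(means, means[0] * np.exp(-0.1 * t), rtol=1e-9)

    def test_crossing_calibration_poisson_expectation(self, movie_scene):
        # over many event logs the analytic crossing count per 5-um line at
        # 3 um offset within 10 s has mean lambda, within 3 SE
        lam, v, n_logs = 5.0, 0.6, 300
        truth = GroundTruth(comet_speed=v, comet_emission=lam, noise=NOISELESS)
        mid_len = 14.0
        counts = []
        for seed in range(n_logs):
            log = draw_comet_events(movie_scene, truth, 10.0, seed)
            # analytic crossing rule with track splay: the distance-from-midline
            # speed is v*cos(a) and the comet drifts laterally by 3*tan(a)
            a = np.deg2rad(log.angle_deg.to_numpy())
            lateral_at_cross = (
                log.lateral_um.to_numpy() - log.side_sign.to_numpy() * 3.0 * np.tan(a)
            )
            t_cross = log.time_s.to_numpy() + 3.0 / (v * np.cos(a))
            crossed = (np.abs(lateral_at_cross - mid_len / 2) <= 2.5) & (t_cross <= 10.0)
            for side in ("left", "right"):
                counts.append(int((crossed & (log.side == side)).sum()))
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - lam) <= 3 * se


class TestFociImage:
    def test_planted_centers_recorded(self, still_scene):
        truth = GroundTruth(foci_count=3)
        _, ann = generate_foci_image(still_scene, truth, seed=1)
        assert len(ann.foci_centers) == 3

    def test_spot_separation_respected(self, still_scene):
        truth = GroundTruth(foci_count=6)
        _, ann = generate_foci_image(still_scene, truth, seed=2, min_separation=1.5)
        pts = np.asarray(ann.foci_centers)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 1.5

    def test_nuclei_two_tier_layout(self, still_scene):
        truth = GroundTruth(nucleus_count=16)
        _, ann = generate_foci_image(still_scene, truth, seed=3, kind="nuclei")
        pts = np.asarray(ann.nucleus_centers)
        assert len(pts) == 16
        d = ann.midline.signed_distance(pts[:, 0], pts[:, 1])
        assert (d < 0).sum() == 8 and (d > 0).sum() == 8
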