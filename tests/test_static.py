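"""Enrichment, depletion, centrosomal ROI, and foci/nucleus counting."""

import dataclasses

import numpy as np
import pytest

from mtocquant.datatypes import GroundTruth, ImageStack
from mtocquant.geometry import circle_mask
from mtocquant.static import (
    DepletionInputs,
    apical_enrichment,
    centrosome_intensity,
    count_foci,
    count_nuclei,
    percent_depletion,
    project_and_subtract,
)
from mtocquant.synthetic import (
    default_annotation,
    generate_depletion_cohort,
    generate_foci_image,
    generate_primordium_image,
    gut_mask,
)
from mtocquant.static import depletion_inputs_from_cohort
from tests.conftest import NOISELESS


class TestEnrichment:
    def test_uniform_gut_gives_ratio_one(self, still_scene):
        ann = default_annotation(still_scene)
        img = np.full(still_scene.image_shape, 50.0)
        res = apical_enrichment(img, ann, slide_bg=10.0, pixel_size=still_scene.pixel_size)
        assert res.ratio == pytest.approx(1.0)

    def test_noiseless_generated_ratio_exact(self, still_scene, clean_truth):
        stacks, ann, _ = generate_primordium_image(still_scene, clean_truth, seed=0)
        img, _ = project_and_subtract(stacks, ann)
        res = apical_enrichment(img, ann, 0.0, still_scene.pixel_size)
        assert res.ratio == pytest.approx(3.0, abs=1e-6)

    def test_global_scaling_invariance_and_apical_equivariance(self, still_scene):
        ann = default_annotation(still_scene)
        rng = np.random.default_rng(3)
        img = rng.uniform(40, 60, size=still_scene.image_shape)
        ps = still_scene.pixel_size
        base = apical_enrichment(img, ann, 0.0, ps).ratio
        scaled = apical_enrichment(3.0 * img, ann, 0.0, ps).ratio
        assert scaled == pytest.approx(base, rel=1e-12)
        boosted = img.copy()
        boosted[ann.apical_box.mask(img.shape, ps)] *= 2.0
        assert apical_enrichment(boosted, ann, 0.0, ps).ratio == pytest.approx(
            2.0 * base, rel=1e-12
        )

    def test_oversubtraction_raises(self, still_scene):
        ann = default_annotation(still_scene)
        img = np.full(still_scene.image_shape, 5.0)
        with pytest.raises(ValueError, match="over-subtracted"):
            apical_enrichment(img, ann, slide_bg=10.0, pixel_size=still_scene.pixel_size)


class TestPercentDepletion:
    def test_zero_minus_signal_is_full_depletion(self):
        minus = DepletionInputs(np.array([5.0, 5.0]), np.array([5.0, 5.0]), 0.0)
        plus = DepletionInputs(np.array([20.0]), np.array([5.0]), 0.0)
        assert percent_depletion(minus, plus) == pytest.approx(100.0)

    def test_identical_cohorts_zero(self):
        d = DepletionInputs(np.array([20.0, 22.0]), np.array([5.0, 5.0]), 2.0)
        assert percent_depletion(d, d) == pytest.approx(0.0)

    def test_negative_minus_clamped_with_warning(self):
        minus = DepletionInputs(np.array([4.0]), np.array([5.0]), 1.0)
        plus = DepletionInputs(np.array([20.0]), np.array([5.0]), 1.0)
        with pytest.warns(UserWarning, match="clamping"):
            assert percent_depletion(minus, plus) == pytest.approx(100.0)

    def test_nonpositive_plus_signal_raises(self):
        d = DepletionInputs(np.array([5.0]), np.array([5.0]), 1.0)
        with pytest.raises(ValueError, match="undefined"):
            percent_depletion(d, d)

    def test_noiseless_recovery_equals_100_delta_and_monotone(self, still_scene):
        recovered = []
        for delta in (0.2, 0.5, 0.931):
            truth = GroundTruth(depletion_fraction=delta, haze_level=20.0,
                                autofluo_level=10.0, embryo_cv=0.0, noise=NOISELESS)
            minus, plus, controls, _ = generate_depletion_cohort(
                still_scene, truth, 2, 2, seed=0, n_controls=2
            )
            dm = depletion_inputs_from_cohort(minus, controls)
            dp = depletion_inputs_from_cohort(plus, controls)
            recovered.append(percent_depletion(dm, dp))
            assert recovered[-1] == pytest.approx(100.0 * delta, abs=1e-9)
        assert recovered == sorted(recovered)


class TestCentrosomeIntensity:
    def test_uniform_stack(self):
        stack = ImageStack(np.full((3, 21, 21), 7.0), 0.11, 0.5)
        assert centrosome_intensity(stack, (10.0, 10.0)) == pytest.approx(7.0)

    def test_planted_spot_matches_pixel_enumeration(self, rng):
        data = rng.uniform(0, 10, size=(4, 31, 31))
        rr, cc = np.mgrid[0:31, 0:31]
        data[2] += 50.0 * np.exp(-((rr - 15) ** 2 + (cc - 15) ** 2) / 8.0)
        stack = ImageStack(data, 0.11, 0.5)
        got = centrosome_intensity(stack, (15.0, 15.0), slide_bg=1.0)
        member = [
            (r, c) for r in range(31) for c in range(31)
            if (r - 15) ** 2 + (c - 15) ** 2 <= 3.5 ** 2
        ]
        assert len(member) == 37
        brute = max(
            np.mean([data[z, r, c] for r, c in member]) for z in range(4)
        ) - 1.0
        assert got == pytest.approx(brute, abs=1e-12)

    def test_clipped_roi_rejected(self):
        stack = ImageStack(np.zeros((2, 10, 10)), 0.11, 0.5)
        with pytest.raises(ValueError, match="clipped"):
            centrosome_intensity(stack, (1.0, 5.0))

    def test_circle_mask_consistency(self):
        assert circle_mask((15, 15), (7, 7), 3.5).sum() == 37


class TestCounting:
    def test_blank_image_counts_zero(self, still_scene):
        truth = GroundTruth(foci_count=0)
        stack, ann = generate_foci_image(still_scene, truth, seed=0)
        region = gut_mask(still_scene, ann.midline)
        n, _ = count_foci(stack.data[0], still_scene.pixel_size, region=region)
        assert n == 0

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_planted_foci_recovered_exactly(self, still_scene, k):
        truth = GroundTruth(foci_count=k)
        stack, ann = generate_foci_image(still_scene, truth, seed=k, min_separation=2.0)
        region = gut_mask(still_scene, ann.midline)
        n, centers = count_foci(stack.data[0], still_scene.pixel_size, region=region)
        assert n == k
        # every detection within half a minimum separation of a planted spot
        ps = still_scene.pixel_size
        planted = np.asarray(ann.foci_centers) / ps
        for rc in centers:
            xy = rc[::-1]
            assert np.min(np.linalg.norm(planted - xy, axis=1)) * ps < 0.5

    def test_two_close_spots_merge_to_one(self, still_scene):
        stack, ann = generate_foci_image(
            still_scene, GroundTruth(), seed=1,
            planted_centers=[(14.0, 14.0), (14.2, 14.0)],
        )
        region = gut_mask(still_scene, ann.midline)
        n, _ = count_foci(stack.data[0], still_scene.pixel_size, region=region)
        assert n == 1

    @pytest.mark.parametrize("k", [4, 16])
    def test_nucleus_counts_recovered(self, still_scene, k):
        truth = GroundTruth(nucleus_count=k)
        stack, ann = generate_foci_image(
            still_scene, truth, seed=5, kind="nuclei",
            spot_sigma=0.4, spot_amplitude=200.0,
        )
        region = gut_mask(still_scene, ann.midline)
        n, _ = count_nuclei(stack.data[0], still_scene.pixel_size, region=region)
        assert n == k
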