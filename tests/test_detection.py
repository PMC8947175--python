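"""Binarization, puncta measurement/classification and the detect pipeline."""

import dataclasses
import warnings

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from mitopuncta import (
    CalibrationFactors,
    ChannelStack,
    DetectionParams,
    SubtractedImage,
    binarize,
    detect,
    find_puncta,
    preset,
    render,
)
from _oracles import classify_components_brute, otsu_brute
from conftest import match_puncta

FAC = CalibrationFactors(x=1.0, y=1.0)


def _sub(values):
    return SubtractedImage(np.asarray(values, dtype=float), "subtract2", FAC)


class TestBinarize:
    def test_two_level_image(self):
        vals = np.zeros((10, 10))
        vals[3:5, 3:5] = 1.0
        mask = binarize(_sub(vals))
        np.testing.assert_array_equal(mask, vals == 1.0)

    def test_fixed_threshold_inclusive(self):
        params = DetectionParams(threshold_method="fixed", fixed_threshold=0.5)
        mask = binarize(_sub([[0.49, 0.5, 0.51]]), params)
        np.testing.assert_array_equal(mask, [[False, True, True]])

    def test_all_zero_warns_empty_mask(self):
        with pytest.warns(UserWarning, match="all-zero"):
            mask = binarize(_sub(np.zeros((8, 8))))
        assert not mask.any()

    def test_otsu_matches_exhaustive_search(self):
        """Bimodal image: library threshold equals exhaustive inter-class
        variance maximisation over 256 bins, and falls between the modes."""
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0.1, 0.05, 3000),
                               rng.normal(0.9, 0.05, 3000)])
        vals = np.clip(vals, 1e-6, None).reshape(60, 100)
        mask = binarize(_sub(vals))
        t_oracle = otsu_brute(vals[vals > 0])
        # the objective is flat over the empty gap between the modes, so the
        # threshold may sit anywhere strictly between them
        assert 0.1 < t_oracle < 0.9
        np.testing.assert_array_equal(mask, vals >= t_oracle)


class TestFindPuncta:
    def test_square_area_in_range(self):
        """A 3x3 solid square at 0.5 um/px has area 2.25 um² and is kept."""
        mask = np.zeros((9, 9), dtype=bool)
        mask[3:6, 3:6] = True
        puncta = find_puncta(mask, np.zeros((9, 9)), FAC, 0.5)
        assert len(puncta) == 1
        p = puncta[0]
        assert p.area_um2 == pytest.approx(2.25)
        assert p.classification == "ectopic_mito"

    def test_single_pixel_rejected_by_size(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        (p,) = find_puncta(mask, np.zeros((5, 5)), FAC, 0.5)
        assert p.area_um2 == pytest.approx(0.25)
        assert p.classification == "rejected_size"

    def test_annulus_is_donut(self):
        mask = np.zeros((31, 31), dtype=bool)
        rr, cc = draw_disk((15, 15), 8)
        mask[rr, cc] = True
        rr, cc = draw_disk((15, 15), 4)
        mask[rr, cc] = False
        (p,) = find_puncta(mask, np.zeros((31, 31)), FAC, 0.25)
        assert p.euler_number == 0
        assert p.classification == "nuclear_origin_donut"

    def test_annulus_kept_when_donut_rule_off(self):
        mask = np.zeros((31, 31), dtype=bool)
        rr, cc = draw_disk((15, 15), 8)
        mask[rr, cc] = True
        rr, cc = draw_disk((15, 15), 4)
        mask[rr, cc] = False
        params = DetectionParams(exclude_donuts=False)
        (p,) = find_puncta(mask, np.zeros((31, 31)), FAC, 0.25, params)
        assert p.classification == "ectopic_mito"

    def test_disc_circularity_near_one(self):
        mask = np.zeros((31, 31), dtype=bool)
        rr, cc = draw_disk((15, 15), 10)
        mask[rr, cc] = True
        (p,) = find_puncta(mask, np.zeros((31, 31)), FAC, 0.2)
        assert p.circularity >= 0.9

    def test_histone_overlap_classification(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:11, 5:11] = True  # 36 px = 2.25 um² at 0.25 um/px
        h2b = np.zeros((20, 20))
        h2b[5:11, 5:11] = 1.0  # fully histone-positive
        h2b[0:3, 0:3] = 0.01   # background class for the threshold
        (p,) = find_puncta(mask, h2b, FAC, 0.25)
        assert p.histone_overlap_fraction == pytest.approx(1.0)
        assert p.classification == "nuclear_origin_overlap"

    def test_size_rule_precedes_donut_rule(self):
        """An out-of-size annulus is rejected_size, not donut (precedence)."""
        mask = np.zeros((41, 41), dtype=bool)
        rr, cc = draw_disk((20, 20), 16)
        mask[rr, cc] = True
        rr, cc = draw_disk((20, 20), 8)
        mask[rr, cc] = False
        (p,) = find_puncta(mask, np.zeros((41, 41)), FAC, 0.25)
        assert p.area_um2 > 20
        assert p.classification == "rejected_size"

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError, match="shape"):
            find_puncta(np.zeros((4, 4), dtype=bool), np.zeros((5, 5)), FAC, 0.25)


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_masks_match_oracle(self, seed):
        """Classifications on random blob masks equal a per-pixel
        reimplementation of every rule (size, shape, donut, overlap)."""
        rng = np.random.default_rng(seed)
        from scipy.ndimage import gaussian_filter

        shape = (rng.integers(12, 33), rng.integers(12, 33))
        mask = gaussian_filter(rng.random(shape), 1.2) > rng.uniform(0.45, 0.6)
        h2b = np.zeros(shape)
        h2b[gaussian_filter(rng.random(shape), 2.0) > 0.55] = 1.0
        h2b[0, 0] = 0.01  # anchor a background class for the Otsu threshold
        px = float(rng.uniform(0.3, 0.7))

        puncta = find_puncta(mask, h2b, FAC, px)
        # two-level histone channel: any sensible threshold separates the
        # levels, so the oracle's own histogram search gives the same mask
        histone_positive = h2b >= otsu_brute(h2b[h2b > 0])
        oracle = classify_components_brute(mask, histone_positive, px)

        got = {}
        for p in puncta:
            n_px = round(p.area_um2 / px**2)
            got[p.label] = (n_px, p.classification, p.euler_number,
                            p.histone_overlap_fraction)
        assert len(got) == len(oracle)
        oracle_sorted = sorted(
            (v[0], v[5], v[3], v[4]) for v in oracle.values()
        )
        got_sorted = sorted(got.values())
        for (n1, c1, e1, o1), (n2, c2, e2, o2) in zip(got_sorted, oracle_sorted):
            assert n1 == n2
            assert c1 == c2
            assert e1 == e2
            assert o1 == pytest.approx(o2, abs=1e-12)


class TestDetectPipeline:
    def test_recovers_ground_truth_counts(self, factors):
        spec = dataclasses.replace(
            preset("tfam_kd", 11), n_ectopic_puncta=5,
            ectopic_area_range_um2=(4.0, 10.0),
        )
        stack, truth = render(spec)
        result = detect(stack, factors)
        assert result.n_ectopic == 5
        matched, fp = match_puncta(result, truth)
        assert matched == 5 and fp == 0

    def test_histone_dots_excluded_not_counted(self, factors):
        spec = dataclasses.replace(
            preset("tfam_kd", 11), n_ectopic_puncta=5,
            ectopic_area_range_um2=(4.0, 10.0),
        )
        base = detect(render(spec)[0], factors)
        withdots = detect(
            render(dataclasses.replace(spec, n_nuclear_dots=3))[0], factors
        )
        assert withdots.n_ectopic == base.n_ectopic == 5
        n_overlap = sum(p.classification == "nuclear_origin_overlap"
                        for p in withdots.puncta)
        assert n_overlap == 3

    def test_empty_field_zero_detections(self, factors):
        stack, _ = render(SceneSpec_empty())
        result = detect(stack, factors)
        assert result.n_ectopic == 0

    def test_translation_invariance(self, factors):
        """Embedding the field at two offsets in a larger blank canvas gives
        the same ectopic count (and the blank area adds no cells)."""
        stack, _ = render(dataclasses.replace(preset("tfam_kd", 13),
                                              n_ectopic_puncta=6))
        counts = []
        cells = []
        for dr, dc in ((0, 0), (13, 17)):
            channels = {}
            for role in ("dsdna", "h2b", "hsp60"):
                canvas = np.zeros((300, 300))
                arr = getattr(stack, role)
                canvas[dr:dr + 256, dc:dc + 256] = arr
                channels[role] = canvas
            shifted = ChannelStack(pixel_size_um=stack.pixel_size_um, **channels)
            res = detect(shifted, factors)
            counts.append(res.n_ectopic)
            cells.append(res.n_cells)
        assert counts[0] == counts[1]
        assert cells[0] == cells[1]

    def test_adding_one_punctum_adds_one(self, factors):
        for seed in (21, 22, 23):
            base = dataclasses.replace(preset("tfam_kd", seed),
                                       n_ectopic_puncta=9,
                                       ectopic_area_range_um2=(4.0, 12.0))
            plus = dataclasses.replace(base, n_ectopic_puncta=10)
            n0 = detect(render(base)[0], factors).n_ectopic
            n1 = detect(render(plus)[0], factors).n_ectopic
            assert n1 == n0 + 1

    def test_colocalized_dsdna_immunity(self, factors):
        """Extra dsDNA inside mitochondria, capped at x*Hsp60, is invisible."""
        spec = dataclasses.replace(preset("tfam_kd", 31), n_ectopic_puncta=6)
        stack, _ = render(spec)
        base = detect(stack, factors)
        boosted_ds = np.where(
            stack.hsp60 > 0.3,
            np.maximum(stack.dsdna, factors.x * stack.hsp60),
            stack.dsdna,
        )
        boosted = ChannelStack(dsdna=boosted_ds, h2b=stack.h2b, hsp60=stack.hsp60,
                               pixel_size_um=stack.pixel_size_um)
        assert detect(boosted, factors).n_ectopic == base.n_ectopic

    def test_variant_subtract1_matches_subtract2(self, factors):
        """With histone discrimination mandatory (subtract1) both variants
        count the same histone-negative puncta."""
        spec = dataclasses.replace(preset("gba_kd", 41),
                                   ectopic_area_range_um2=(4.0, 12.0))
        stack, truth = render(spec)
        r1 = detect(stack, factors, variant="subtract1")
        r2 = detect(stack, factors, variant="subtract2")
        n_gt = len(truth.of_type("ectopic_punctum"))
        assert r1.n_ectopic == r2.n_ectopic == n_gt

    def test_nucleus_params_cross_validation(self, factors):
        from mitopuncta import NucleusParams

        stack, _ = render(preset("control", 51))
        with pytest.raises(ValueError, match="nucleus"):
            detect(stack, factors,
                   nucleus_params=NucleusParams(min_nucleus_area_um2=10.0))


def SceneSpec_empty():
    from mitopuncta import SceneSpec

    return SceneSpec(n_cells=3, n_ectopic_puncta=0, seed=77)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_area_um2": 0.0},
            {"min_area_um2": 25.0},
            {"min_circularity": -0.1},
            {"max_circularity": 1.2},
            {"connectivity": 6},
            {"threshold_method": "fixed"},
            {"histone_overlap_max_fraction": 1.5},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DetectionParams(**kwargs)
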