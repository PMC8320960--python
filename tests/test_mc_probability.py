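"""Background estimation, percentile selections and mask algebra, each
checked against independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from oracles import erosion_oracle

from mcclassify.io_formats import ImagePatch
from mcclassify.mc_probability import (
    DifferenceImage,
    bicubic_smooth,
    cleanup,
    combine,
    difference_image,
    estimate_background,
    highpass_filter,
    highpass_kernel,
    image_b,
    low_contrast_fallback,
    probability_image,
    select_top_fraction,
)


class TestEstimateBackground:
    def test_constant_image(self, flat_patch):
        bg = estimate_background(flat_patch, subregion_px=30)
        assert np.allclose(bg.surface, 100.0, atol=1e-8)
        diff = difference_image(flat_patch, bg)
        assert np.allclose(diff.pixels, 0.0, atol=1e-8)

    def test_linear_ramp_reproduced(self):
        rr, cc = np.indices((120, 120))
        ramp = 100.0 + 5.0 * rr / 119 * 100 + 2.0 * cc / 119 * 100
        patch = ImagePatch(ramp, spacing_um=70.0)
        bg = estimate_background(patch, subregion_px=30)
        rng_span = ramp.max() - ramp.min()
        assert np.abs(bg.surface - ramp).max() < 0.01 * rng_span

    def test_small_blob_suppressed(self, blob_patch):
        bg = estimate_background(blob_patch, subregion_px=30)
        diff = difference_image(blob_patch, bg)
        hot = np.abs(diff.pixels) > 10
        rr, cc = np.nonzero(hot)
        assert hot.any()
        # every strong difference pixel lies near the planted blob
        assert rr.min() >= 25 and rr.max() <= 40
        assert cc.min() >= 35 and cc.max() <= 50

    def test_subregion_larger_than_image_rejected(self, flat_patch):
        with pytest.raises(ValueError):
            estimate_background(flat_patch, subregion_px=100)


class TestSelectTopFraction:
    def test_distinct_values_match_sorting_oracle(self):
        vals = np.arange(1.0, 101.0).reshape(10, 10)
        diff = DifferenceImage(pixels=vals.copy())
        mask = select_top_fraction(diff, fraction=0.05)
        assert mask.sum() == 5
        assert set(vals[mask]) == {96.0, 97.0, 98.0, 99.0, 100.0}
        assert diff.threshold_t == 96.0

    def test_no_positive_pixels(self):
        diff = DifferenceImage(pixels=-np.ones((5, 5)))
        with pytest.warns(UserWarning):
            mask = select_top_fraction(diff)
        assert not mask.any() and diff.threshold_t is None

    def test_fraction_one_selects_all_positives(self, rng):
        vals = rng.normal(size=(20, 20))
        diff = DifferenceImage(pixels=vals)
        mask = select_top_fraction(diff, fraction=1.0)
        assert mask.sum() == (vals > 0).sum()

    @pytest.mark.parametrize("trial", range(10))
    def test_count_contract_random(self, trial):
        rng = np.random.default_rng(trial)
        vals = rng.normal(size=(15, 17))
        f = rng.uniform(0.01, 1.0)
        diff = DifferenceImage(pixels=vals)
        mask = select_top_fraction(diff, fraction=f)
        n_pos = (vals > 0).sum()
        assert mask.sum() == int(np.ceil(f * n_pos))
        # selected values are all >= every unselected positive value
        assert vals[mask].min() >= vals[(vals > 0) & ~mask].max() - 1e-12


class TestCleanup:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        assert not cleanup(mask).any()

    def test_solid_square_erodes(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True
        out = cleanup(mask)
        expect = np.zeros_like(mask)
        expect[3:6, 3:6] = True
        assert np.array_equal(out, expect)

    @pytest.mark.parametrize("trial", range(5))
    def test_erosion_matches_neighbourhood_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        mask = rng.uniform(size=(50, 50)) > 0.3
        from scipy import ndimage as ndi

        out = ndi.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
        assert np.array_equal(out, erosion_oracle(mask, 3, anchored=False))

    def test_never_adds_pixels(self, rng):
        mask = rng.uniform(size=(40, 40)) > 0.4
        out = cleanup(mask)
        assert not (out & ~mask).any()


class TestLowContrastFallback:
    def test_large_mask_unchanged(self, rng):
        mask = rng.uniform(size=(10, 10)) > 0.8
        mask[:4] = True  # ensure >= 15% coverage
        diff = DifferenceImage(pixels=rng.normal(size=(10, 10)), threshold_t=1.0)
        assert np.array_equal(low_contrast_fallback(mask, diff), mask)

    def test_relaxed_threshold_pixels_added(self):
        vals = np.linspace(0, 99, 100).reshape(10, 10)
        diff = DifferenceImage(pixels=vals, threshold_t=40.0)
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, :3] = True
        out = low_contrast_fallback(mask, diff)
        assert np.array_equal(out, mask | (vals > 20.0))

    def test_empty_mask_stays_empty_when_nothing_qualifies(self):
        diff = DifferenceImage(pixels=np.full((10, 10), 5.0), threshold_t=40.0)
        out = low_contrast_fallback(np.zeros((10, 10), dtype=bool), diff)
        assert not out.any()

    def test_undefined_threshold_warns_and_passes_through(self):
        diff = DifferenceImage(pixels=np.zeros((10, 10)))
        mask = np.zeros((10, 10), dtype=bool)
        with pytest.warns(UserWarning):
            out = low_contrast_fallback(mask, diff)
        assert not out.any()


class TestHighpass:
    def test_kernel_is_zero_sum_centre_80(self):
        k = highpass_kernel()
        assert k.shape == (9, 9) and k[4, 4] == 80.0
        assert k.sum() == 0.0

    def test_constant_surface_zero_response(self):
        out = highpass_filter(np.full((20, 20), 123.0))
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_impulse_response(self):
        surface = np.zeros((21, 21))
        surface[10, 10] = 1.0
        out = highpass_filter(surface)
        assert out[10, 10] == pytest.approx(80.0)
        assert out[10, 11] == pytest.approx(-1.0)
        assert out[6, 6] == pytest.approx(-1.0)
        assert out[10, 15] == pytest.approx(0.0)

    def test_matches_double_loop_convolution_oracle(self, rng):
        surface = rng.normal(size=(20, 20))
        out = highpass_filter(surface)
        k = highpass_kernel()
        # interior pixels only: avoids committing the oracle to a
        # particular boundary extension
        for i in range(4, 16):
            for j in range(4, 16):
                acc = 0.0
                for di in range(-4, 5):
                    for dj in range(-4, 5):
                        acc += k[4 + di, 4 + dj] * surface[i - di, j - dj]
                assert out[i, j] == pytest.approx(acc, rel=1e-9, abs=1e-9)


class TestImageBAndCombine:
    def test_count_contract(self, rng):
        out = image_b(rng.normal(size=(20, 20)), fraction=0.05)
        assert out.sum() == 20

    def test_distinct_values_match_sorting_oracle(self, rng):
        vals = rng.permutation(400).astype(float).reshape(20, 20)
        out = image_b(vals, fraction=0.05)
        assert set(vals[out]) == set(range(380, 400))

    def test_fraction_one_selects_everything(self, rng):
        assert image_b(rng.normal(size=(7, 7)), fraction=1.0).all()

    def test_combine_is_conjunction(self, rng):
        a = rng.uniform(size=(15, 15)) > 0.5
        b = rng.uniform(size=(15, 15)) > 0.5
        c = combine(a, b)
        assert np.array_equal(c, a & b)
        assert not (c & ~a).any() and not (c & ~b).any()

    def test_combine_identity_and_disjoint(self):
        b = np.zeros((5, 5), dtype=bool)
        b[2, 2] = True
        assert np.array_equal(combine(np.ones((5, 5), dtype=bool), b), b)
        a = np.zeros((5, 5), dtype=bool)
        a[0, 0] = True
        assert not combine(a, b).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine(np.zeros((4, 4), dtype=bool), np.zeros((5, 5), dtype=bool))


class TestFullChain:
    def test_high_contrast_blobs_reach_image_c(self, phantom_roi):
        out = probability_image(phantom_roi.patch)
        sigma = 8.0
        from mcclassify.cluster_rules import label_blobs

        truth_blobs = label_blobs(phantom_roi.truth_mask)
        c = out["image_c"]
        missed = 0
        for blob, rec in zip(truth_blobs.blobs, phantom_roi.blobs):
            if rec.contrast >= 3 * sigma and rec.diameter_px >= 3:
                if not c[blob.coords[:, 0], blob.coords[:, 1]].any():
                    missed += 1
        assert missed == 0

    def test_smooth_step_one_is_identity(self, blob_patch):
        assert np.allclose(bicubic_smooth(blob_patch, step_px=1),
                           blob_patch.pixels)
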