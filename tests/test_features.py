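"""Registry structure and geometric/texture feature correctness."""

from __future__ import annotations

import numpy as np
import pytest
from oracles import glcm_contrast_oracle, shoelace_area
from skimage.draw import disk

from mcclassify.cluster_rules import label_blobs
from mcclassify.features import (
    N_FEATURES,
    blob_properties,
    cluster_properties,
    extract_features,
    feature_registry,
    glcm_features,
    registry_table,
    texture_features,
)
from mcclassify.io_formats import DataError, ImagePatch


def _patch_from(pixels: np.ndarray) -> ImagePatch:
    return ImagePatch(pixels.astype(np.float64), spacing_um=70.0, bit_depth=12)


def _uniform_patch(shape=(64, 64), value=500.0) -> ImagePatch:
    return _patch_from(np.full(shape, value))


class TestRegistry:
    def test_partition_17_17_17(self):
        reg = feature_registry()
        assert len(reg) == N_FEATURES == 51
        counts = {"size": 0, "shape": 0, "texture": 0}
        for f in reg:
            counts[f.category] += 1
        assert counts == {"size": 17, "shape": 17, "texture": 17}

    def test_names_unique_and_exported(self):
        table = registry_table()
        assert table["name"].is_unique
        assert set(table.columns) == {"name", "category", "definition"}


class TestBlobProperties:
    def test_disk_is_round(self):
        mask = np.zeros((40, 40), dtype=bool)
        rr, cc = disk((20, 20), 10)
        mask[rr, cc] = True
        df = blob_properties(_uniform_patch((40, 40)), label_blobs(mask))
        assert df.loc[0, "eccentricity"] < 0.2
        assert 0.85 <= df.loc[0, "circularity"] <= 1.1

    def test_line_blob_is_elongated(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10, 5:25] = True
        df = blob_properties(_uniform_patch((30, 30)), label_blobs(mask))
        assert df.loc[0, "elongation"] >= 10
        assert df.loc[0, "eccentricity"] > 0.99

    def test_single_pixel_degenerate_values(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 4] = True
        df = blob_properties(_uniform_patch((10, 10)), label_blobs(mask))
        row = df.iloc[0]
        assert row["area"] == 1
        assert row["eccentricity"] == 0.0
        assert row["elongation"] == 1.0
        assert row["circularity"] == 1.0

    def test_crack_perimeter_of_square(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[3:7, 3:7] = True  # 4x4 square: 16 exposed edges
        df = blob_properties(_uniform_patch((12, 12)), label_blobs(mask))
        assert df.loc[0, "perimeter"] == 16

    def test_empty_blobset_rejected(self):
        with pytest.raises(DataError):
            blob_properties(_uniform_patch(), label_blobs(np.zeros((64, 64),
                                                                   bool)))


class TestClusterProperties:
    def test_corner_blobs_hull_matches_shoelace(self):
        mask = np.zeros((100, 100), dtype=bool)
        for r, c in [(0, 0), (0, 99), (99, 0), (99, 99)]:
            mask[r, c] = True
        cl = cluster_properties(label_blobs(mask))
        corners = np.array([[0, 0], [0, 99], [99, 99], [99, 0]], float)
        assert cl["hull_area"] == pytest.approx(shoelace_area(corners))
        assert cl["hull_area"] == pytest.approx(9801.0)

    def test_concentric_blobs_zero_distance_spread(self):
        mask = np.zeros((40, 40), dtype=bool)
        # four blobs at the corners of a centred square: all centroids
        # equidistant from the cluster centroid
        for r, c in [(10, 10), (10, 28), (28, 10), (28, 28)]:
            mask[r : r + 2, c : c + 2] = True
        cl = cluster_properties(label_blobs(mask))
        assert cl["dist_std"] == pytest.approx(0.0, abs=1e-9)

    def test_distance_scales_linearly(self):
        def mean_dist(spread: int) -> float:
            mask = np.zeros((200, 200), dtype=bool)
            for r, c in [(100 - spread, 100), (100 + spread, 100),
                         (100, 100 - spread), (100, 100 + spread)]:
                mask[r, c] = True
            return cluster_properties(label_blobs(mask))["dist_mean"]

        assert mean_dist(40) == pytest.approx(2 * mean_dist(20))


class TestTexture:
    def test_constant_region_limits(self):
        patch = _uniform_patch((20, 20))
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        tex = texture_features(patch, mask)
        assert tex["intensity_std"] == 0.0
        assert tex["glcm_energy"] == pytest.approx(1.0)
        assert tex["glcm_contrast"] == pytest.approx(0.0)

    def test_glcm_contrast_matches_pair_count_oracle(self, rng):
        region = rng.integers(0, 4096, size=(16, 16)).astype(np.float64)
        from mcclassify.features import GLCM_LEVELS, _quantize
        from skimage.feature import graycomatrix, graycoprops

        q = _quantize(region, GLCM_LEVELS)
        glcm = graycomatrix(q, distances=[1], angles=[0], levels=GLCM_LEVELS,
                            symmetric=True, normed=True)
        contrast = float(graycoprops(glcm, "contrast")[0, 0])
        assert contrast == pytest.approx(glcm_contrast_oracle(q, 0, 1))

    def test_intensity_rescaling_leaves_glcm_unchanged(self, rng):
        region = rng.integers(0, 2048, size=(20, 20)).astype(np.float64)
        a = glcm_features(region)
        b = glcm_features(region * 2.0)
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(DataError):
            texture_features(_uniform_patch(), np.zeros((64, 64), bool))


class TestExtractFeatures:
    def _segmented(self, shift=(0, 0), scale=1):
        pixels = np.full((120, 120), 500.0)
        mask = np.zeros((120, 120), dtype=bool)
        for r, c in [(30, 30), (30, 70), (70, 50)]:
            rr = r * 1 + shift[0]
            cc = c * 1 + shift[1]
            size = 4 * scale
            mask[rr : rr + size, cc : cc + size] = True
            pixels[rr : rr + size, cc : cc + size] = 900.0
        return _patch_from(pixels), mask

    def test_vector_has_51_entries(self):
        patch, mask = self._segmented()
        vec = extract_features(patch, mask)
        assert vec.values.shape == (51,)
        assert np.isfinite(vec.values).all()

    def test_translation_invariance_of_geometry(self):
        patch, mask = self._segmented()
        patch2, mask2 = self._segmented(shift=(7, 11))
        v1 = extract_features(patch, mask)
        v2 = extract_features(patch2, mask2)
        geometric = [f.name for f in feature_registry()
                     if f.category in ("size", "shape")]
        for name in geometric:
            i = v1.names.index(name)
            assert v1.values[i] == pytest.approx(v2.values[i], rel=1e-9), name

    def test_doubled_blobs_quadruple_mean_area(self):
        patch1, mask1 = self._segmented()
        patch2, mask2 = self._segmented(scale=2)
        v1 = extract_features(patch1, mask1)
        v2 = extract_features(patch2, mask2)
        i = v1.names.index("blob_area_mean")
        assert v2.values[i] == pytest.approx(4 * v1.values[i], rel=0.05)

    def test_shape_features_scale_invariant_for_disks(self):
        def disk_vec(radius: int):
            pixels = np.full((200, 200), 400.0)
            mask = np.zeros((200, 200), dtype=bool)
            for centre in [(50, 50), (50, 150), (150, 100)]:
                rr, cc = disk(centre, radius)
                mask[rr, cc] = True
                pixels[rr, cc] = 900.0
            return extract_features(_patch_from(pixels), mask)

        v1, v2 = disk_vec(8), disk_vec(16)
        for name in ("blob_eccentricity_mean", "blob_elongation_mean",
                     "blob_circularity_mean"):
            i = v1.names.index(name)
            denom = max(abs(v1.values[i]), 1e-9)
            assert abs(v1.values[i] - v2.values[i]) / denom <= 0.05, name

    def test_deterministic(self):
        patch, mask = self._segmented()
        v1 = extract_features(patch, mask)
        v2 = extract_features(patch, mask)
        assert np.array_equal(v1.values, v2.values)

    def test_empty_segmentation_rejected(self):
        patch, _ = self._segmented()
        with pytest.raises(DataError):
            extract_features(patch, np.zeros((120, 120), bool))
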