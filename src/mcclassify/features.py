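"""The 51-feature shape / size / texture descriptor of a segmented patch.

Microcalcification clusters are characterised radiologically by the size
of the individual calcifications, their shapes (round and uniform vs
pleomorphic), their spatial distribution inside the cluster, and the
texture of the cluster region.  The descriptor mirrors those axes with an
ordered registry of 51 named features, 17 per category:

* **size** - per-blob area / perimeter / axis statistics, total cluster
  area, convex-hull area and perimeter, blob count and density;
* **shape** - per-blob eccentricity, elongation, circularity, solidity and
  extent statistics, the same moments for the cluster as a whole, and the
  distribution of blob-centroid distances from the cluster centroid;
* **texture** - first-order statistics of the segmented pixels, per-blob
  intensity aggregates (including the summation of per-MC mean
  intensities, a proxy for cluster density), and gray-level co-occurrence
  (GLCM) statistics on the cluster bounding box.

The registry order is fixed, so feature vectors are comparable across
runs and exports; ``feature_registry()`` returns it as a table.

Conventions: the *perimeter* feature is the integer crack length (each
exposed pixel edge counts 1, reproducible exactly); *circularity*
``4*pi*A/P**2`` instead uses the Crofton-style perimeter estimate of
``skimage`` so that a rasterised disk scores ~1 (the crack length of any
convex shape equals its bounding half-perimeter, which would bias
circularity low).  Degenerate blobs stay finite: a single pixel has
eccentricity 0, elongation 1, circularity 1; hulls of fewer than 3
non-collinear points fall back to the plain blob area.  GLCM features are
computed on 32 gray levels re-quantised over the observed min-max, making
them independent of bit depth and of global intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import perimeter as smooth_perimeter
from skimage.measure import regionprops

from .cluster_rules import BlobSet, label_blobs
from .io_formats import DataError, ImagePatch

__all__ = [
    "FeatureDef",
    "FeatureVector",
    "feature_registry",
    "registry_table",
    "blob_properties",
    "cluster_properties",
    "texture_features",
    "extract_features",
]

N_FEATURES = 51
N_PER_CATEGORY = 17
GLCM_LEVELS = 32


@dataclass(frozen=True)
class FeatureDef:
    name: str
    category: str  # size | shape | texture
    definition: str


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list[str]
    id: str = ""
    label: str = "unknown"

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.id)


_REGISTRY: list[FeatureDef] = [
    # ------------------------------------------------------------- size
    FeatureDef("blob_area_mean", "size", "mean area of individual MCs (px)"),
    FeatureDef("blob_area_std", "size", "std of individual MC areas"),
    FeatureDef("blob_area_min", "size", "smallest MC area"),
    FeatureDef("blob_area_max", "size", "largest MC area"),
    FeatureDef("cluster_area", "size", "total segmented area (sum of MC areas)"),
    FeatureDef("cluster_hull_area", "size", "convex-hull area over all MC pixels"),
    FeatureDef("cluster_hull_perimeter", "size", "perimeter of the cluster hull"),
    FeatureDef("blob_perimeter_mean", "size", "mean MC crack-length perimeter"),
    FeatureDef("blob_perimeter_std", "size", "std of MC perimeters"),
    FeatureDef("blob_perimeter_total", "size", "summed MC perimeters"),
    FeatureDef("blob_equiv_diameter_mean", "size", "mean equivalent disk diameter"),
    FeatureDef("blob_equiv_diameter_std", "size", "std of equivalent diameters"),
    FeatureDef("blob_major_axis_mean", "size", "mean major ellipse axis"),
    FeatureDef("blob_minor_axis_mean", "size", "mean minor ellipse axis"),
    FeatureDef("blob_count", "size", "number of MCs in the cluster"),
    FeatureDef("cluster_density", "size", "MC count per hull-area pixel"),
    FeatureDef("cluster_bbox_area", "size", "area of the cluster bounding box"),
    # ------------------------------------------------------------ shape
    FeatureDef("blob_eccentricity_mean", "shape", "mean MC eccentricity"),
    FeatureDef("blob_eccentricity_std", "shape", "std of MC eccentricities"),
    FeatureDef("blob_elongation_mean", "shape", "mean major/minor axis ratio"),
    FeatureDef("blob_elongation_std", "shape", "std of axis ratios"),
    FeatureDef("blob_circularity_mean", "shape", "mean 4*pi*A/P^2"),
    FeatureDef("blob_circularity_std", "shape", "std of circularities"),
    FeatureDef("blob_solidity_mean", "shape", "mean area/hull-area per MC"),
    FeatureDef("blob_solidity_std", "shape", "std of solidities"),
    FeatureDef("blob_extent_mean", "shape", "mean area/bbox-area per MC"),
    FeatureDef("cluster_eccentricity", "shape", "eccentricity of the MC union"),
    FeatureDef("cluster_elongation", "shape", "axis ratio of the MC union"),
    FeatureDef("cluster_solidity", "shape", "cluster area / hull area"),
    FeatureDef("cluster_circularity", "shape", "4*pi*hullA/hullP^2"),
    FeatureDef("centroid_distance_mean", "shape",
               "mean MC-centroid distance from the cluster centroid"),
    FeatureDef("centroid_distance_std", "shape", "std of centroid distances"),
    FeatureDef("centroid_distance_var", "shape",
               "variance of the centroid distances (MC distribution)"),
    FeatureDef("centroid_distance_max", "shape", "largest centroid distance"),
    # ---------------------------------------------------------- texture
    FeatureDef("intensity_mean", "texture", "mean intensity of segmented pixels"),
    FeatureDef("intensity_std", "texture", "std of segmented-pixel intensities"),
    FeatureDef("intensity_skewness", "texture", "skewness of intensities"),
    FeatureDef("intensity_kurtosis", "texture", "excess kurtosis of intensities"),
    FeatureDef("intensity_entropy", "texture",
               "Shannon entropy (bits, 32-bin histogram)"),
    FeatureDef("intensity_range", "texture", "max - min segmented intensity"),
    FeatureDef("blob_intensity_mean_sum", "texture",
               "summation of per-MC mean intensities (cluster density proxy)"),
    FeatureDef("blob_intensity_mean_std", "texture", "std of per-MC means"),
    FeatureDef("blob_intensity_mean_min", "texture", "lowest per-MC mean"),
    FeatureDef("blob_intensity_mean_max", "texture", "highest per-MC mean"),
    FeatureDef("blob_intensity_std_mean", "texture", "mean per-MC intensity std"),
    FeatureDef("contrast_to_background", "texture",
               "mean MC intensity minus median local background"),
    FeatureDef("glcm_contrast", "texture", "GLCM contrast (d=1, 4 offsets)"),
    FeatureDef("glcm_correlation", "texture", "GLCM correlation"),
    FeatureDef("glcm_energy", "texture", "GLCM energy"),
    FeatureDef("glcm_homogeneity", "texture", "GLCM homogeneity"),
    FeatureDef("glcm_entropy", "texture", "GLCM entropy (bits)"),
]

assert len(_REGISTRY) == N_FEATURES


def feature_registry() -> list[FeatureDef]:
    return list(_REGISTRY)


def registry_table() -> pd.DataFrame:
    """The registry as a (name, category, definition) table for export."""
    return pd.DataFrame(
        [(f.name, f.category, f.definition) for f in _REGISTRY],
        columns=["name", "category", "definition"],
    )


def feature_names() -> list[str]:
    return [f.name for f in _REGISTRY]


def _crack_perimeter(mask: np.ndarray) -> float:
    """Crack-length boundary: every exposed pixel edge counts 1."""
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    horiz = int((mask[:, :-1] & mask[:, 1:]).sum())
    vert = int((mask[:-1, :] & mask[1:, :]).sum())
    return float(4 * area - 2 * (horiz + vert))


def _blob_mask(blob, shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[blob.coords[:, 0], blob.coords[:, 1]] = True
    return m


def blob_properties(patch: ImagePatch, blobs: BlobSet) -> pd.DataFrame:
    """Per-blob geometry and intensity properties, one row per blob."""
    if len(blobs) == 0:
        raise DataError("no segmented MCs: the patch is unsegmentable")
    pixels = patch.astype_float()
    props = regionprops(blobs.labels, intensity_image=pixels)
    centroids = np.array([b.centroid for b in blobs.blobs])
    cluster_centroid = centroids.mean(axis=0)
    rows = []
    for blob, rp in zip(blobs.blobs, props):
        area = float(rp.area)
        local = pixels[blob.coords[:, 0], blob.coords[:, 1]]
        minor = float(rp.axis_minor_length)
        major = float(rp.axis_major_length)
        if area <= 1:
            ecc, elong, circ = 0.0, 1.0, 1.0
        else:
            ecc = float(rp.eccentricity)
            elong = major / max(minor, 1.0)  # a pixel row is 1 px wide
            sp = smooth_perimeter(_blob_mask(blob, blobs.shape), neighborhood=4)
            circ = 4 * np.pi * area / max(sp, 1.0) ** 2
        d = float(np.hypot(*(np.asarray(blob.centroid) - cluster_centroid)))
        rows.append(
            {
                "label": blob.label,
                "area": area,
                "perimeter": _crack_perimeter(_blob_mask(blob, blobs.shape)),
                "eccentricity": ecc,
                "elongation": elong,
                "circularity": circ,
                "solidity": float(rp.solidity),
                "extent": float(rp.extent),
                "equiv_diameter": float(rp.equivalent_diameter_area),
                "major_axis": major,
                "minor_axis": minor,
                "mean_intensity": float(local.mean()),
                "intensity_std": float(local.std()),
                "centroid_row": float(blob.centroid[0]),
                "centroid_col": float(blob.centroid[1]),
                "centroid_distance": d,
            }
        )
    return pd.DataFrame(rows)


def _hull_geometry(coords: np.ndarray, union: np.ndarray) -> tuple[float, float]:
    """(area, perimeter) of the convex hull of pixel-centre points.

    Degenerate point sets (collinear, < 3 points) fall back to the plain
    pixel area and crack perimeter of the union mask.
    """
    try:
        hull = ConvexHull(np.asarray(coords, dtype=np.float64))
        return float(hull.volume), float(hull.area)
    except (QhullError, ValueError):
        return float(union.sum()), _crack_perimeter(union)


def cluster_properties(blobs: BlobSet, blob_df: pd.DataFrame | None = None) -> dict:
    """Cluster-level geometry: hull, union moments, centroid dispersion."""
    if len(blobs) == 0:
        raise DataError("no segmented MCs: the patch is unsegmentable")
    union = blobs.mask()
    coords = np.argwhere(union)
    hull_area, hull_perimeter = _hull_geometry(coords, union)
    rp = regionprops(union.astype(np.uint8))[0]
    minor = float(rp.axis_minor_length)
    major = float(rp.axis_major_length)
    centroids = np.array([b.centroid for b in blobs.blobs])
    cluster_centroid = centroids.mean(axis=0)
    dists = np.hypot(*(centroids - cluster_centroid).T)
    total_area = float(union.sum())
    return {
        "centroid": tuple(cluster_centroid),
        "area": total_area,
        "hull_area": hull_area,
        "hull_perimeter": hull_perimeter,
        "eccentricity": float(rp.eccentricity) if total_area > 1 else 0.0,
        "elongation": major / max(minor, 1.0) if total_area > 1 else 1.0,
        "solidity": total_area / max(hull_area, 1.0),
        "circularity": 4 * np.pi * hull_area / max(hull_perimeter, 1.0) ** 2,
        "bbox_area": float(
            (np.ptp(coords[:, 0]) + 1) * (np.ptp(coords[:, 1]) + 1)
        ),
        "count": len(blobs),
        "density": len(blobs) / max(hull_area, 1.0),
        "dist_mean": float(dists.mean()),
        "dist_std": float(dists.std()),
        "dist_var": float(dists.var()),
        "dist_max": float(dists.max()),
    }


def _quantize(region: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    lo = region.min()
    hi = region.max()
    if hi <= lo:
        return np.zeros(region.shape, dtype=np.uint8)
    q = np.floor((region - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm_features(region: np.ndarray, levels: int = GLCM_LEVELS) -> dict:
    """Co-occurrence statistics at distance 1, averaged over 4 offsets.

    The region is re-quantised to ``levels`` gray levels over its observed
    min-max, so the result is invariant to affine intensity rescaling.
    """
    q = _quantize(np.asarray(region, dtype=np.float64), levels)
    glcm = graycomatrix(
        q,
        distances=[1],
        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels,
        symmetric=True,
        normed=True,
    )
    p = glcm[:, :, 0, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(
            np.where(p > 0, p * np.log2(p), 0.0), axis=(0, 1)
        )
    return {
        "glcm_contrast": float(graycoprops(glcm, "contrast").mean()),
        "glcm_correlation": float(graycoprops(glcm, "correlation").mean()),
        "glcm_energy": float(graycoprops(glcm, "energy").mean()),
        "glcm_homogeneity": float(graycoprops(glcm, "homogeneity").mean()),
        "glcm_entropy": float(ent.mean()),
    }


def texture_features(
    patch: ImagePatch, mask: np.ndarray, blob_df: pd.DataFrame | None = None
) -> dict:
    """First-order, per-blob-aggregate and GLCM texture statistics."""
    pixels = patch.astype_float()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DataError("texture features need a non-empty mask")
    vals = pixels[mask]
    skew = stats.skew(vals) if vals.size > 2 and vals.std() > 0 else 0.0
    kurt = stats.kurtosis(vals) if vals.size > 3 and vals.std() > 0 else 0.0
    hist, _ = np.histogram(vals, bins=GLCM_LEVELS)
    p = hist[hist > 0] / hist.sum()
    entropy = float(-(p * np.log2(p)).sum())
    coords = np.argwhere(mask)
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0)
    box = pixels[r0 : r1 + 1, c0 : c1 + 1]
    box_mask = mask[r0 : r1 + 1, c0 : c1 + 1]
    bg_vals = box[~box_mask]
    bg_median = float(np.median(bg_vals)) if bg_vals.size else float(
        np.median(pixels[~mask]) if (~mask).any() else 0.0
    )
    out = {
        "intensity_mean": float(vals.mean()),
        "intensity_std": float(vals.std()),
        "intensity_skewness": float(skew),
        "intensity_kurtosis": float(kurt),
        "intensity_entropy": entropy,
        "intensity_range": float(vals.max() - vals.min()),
        "contrast_to_background": float(vals.mean() - bg_median),
    }
    out.update(glcm_features(box))
    if blob_df is not None:
        means = blob_df["mean_intensity"].to_numpy()
        out.update(
            {
                "blob_intensity_mean_sum": float(means.sum()),
                "blob_intensity_mean_std": float(means.std()),
                "blob_intensity_mean_min": float(means.min()),
                "blob_intensity_mean_max": float(means.max()),
                "blob_intensity_std_mean": float(
                    blob_df["intensity_std"].mean()
                ),
            }
        )
    return out


def extract_features(
    patch: ImagePatch, seg: np.ndarray, label: str = "unknown"
) -> FeatureVector:
    """Assemble the ordered 51-feature vector for one segmented patch.

    Raises :class:`DataError` on an empty segmentation (the unsegmentable
    case, which the pipeline excludes and counts).
    """
    blobs = label_blobs(seg)
    if len(blobs) == 0:
        raise DataError(f"patch {patch.id!r}: empty segmentation")
    df = blob_properties(patch, blobs)
    cl = cluster_properties(blobs, df)
    tex = texture_features(patch, blobs.mask(), df)

    def col(name: str, agg: str) -> float:
        return float(getattr(df[name], agg)())

    values = {
        "blob_area_mean": col("area", "mean"),
        "blob_area_std": float(df["area"].std(ddof=0)),
        "blob_area_min": col("area", "min"),
        "blob_area_max": col("area", "max"),
        "cluster_area": cl["area"],
        "cluster_hull_area": cl["hull_area"],
        "cluster_hull_perimeter": cl["hull_perimeter"],
        "blob_perimeter_mean": col("perimeter", "mean"),
        "blob_perimeter_std": float(df["perimeter"].std(ddof=0)),
        "blob_perimeter_total": col("perimeter", "sum"),
        "blob_equiv_diameter_mean": col("equiv_diameter", "mean"),
        "blob_equiv_diameter_std": float(df["equiv_diameter"].std(ddof=0)),
        "blob_major_axis_mean": col("major_axis", "mean"),
        "blob_minor_axis_mean": col("minor_axis", "mean"),
        "blob_count": float(cl["count"]),
        "cluster_density": cl["density"],
        "cluster_bbox_area": cl["bbox_area"],
        "blob_eccentricity_mean": col("eccentricity", "mean"),
        "blob_eccentricity_std": float(df["eccentricity"].std(ddof=0)),
        "blob_elongation_mean": col("elongation", "mean"),
        "blob_elongation_std": float(df["elongation"].std(ddof=0)),
        "blob_circularity_mean": col("circularity", "mean"),
        "blob_circularity_std": float(df["circularity"].std(ddof=0)),
        "blob_solidity_mean": col("solidity", "mean"),
        "blob_solidity_std": float(df["solidity"].std(ddof=0)),
        "blob_extent_mean": col("extent", "mean"),
        "cluster_eccentricity": cl["eccentricity"],
        "cluster_elongation": cl["elongation"],
        "cluster_solidity": cl["solidity"],
        "cluster_circularity": cl["circularity"],
        "centroid_distance_mean": cl["dist_mean"],
        "centroid_distance_std": cl["dist_std"],
        "centroid_distance_var": cl["dist_var"],
        "centroid_distance_max": cl["dist_max"],
        **{k: tex[k] for k in (
            "intensity_mean", "intensity_std", "intensity_skewness",
            "intensity_kurtosis", "intensity_entropy", "intensity_range",
            "blob_intensity_mean_sum", "blob_intensity_mean_std",
            "blob_intensity_mean_min", "blob_intensity_mean_max",
            "blob_intensity_std_mean", "contrast_to_background",
            "glcm_contrast", "glcm_correlation", "glcm_energy",
            "glcm_homogeneity", "glcm_entropy",
        )},
    }
    arr = np.array([values[f.name] for f in _REGISTRY], dtype=np.float64)
    arr = np.nan_to_num(arr, nan=0.0, posinf=0.0, neginf=0.0)
    return FeatureVector(values=arr, names=feature_names(), id=patch.id, label=label)
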