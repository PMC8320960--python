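"""Dice-based evaluation of a segmentation against a radiologist outline.

The reference mask is the filled annotation polygon (boundary pixels
included).  Individual segmented MCs whose centroid lies inside the
reference are gathered and their filled convex hull is compared with the
reference mask by the Dice similarity coefficient

    Dice = 2 |X ∩ Y| / (|X| + |Y|).

Two empty masks are defined to agree perfectly (Dice 1): both raters
report an absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter
from skimage.morphology import convex_hull_image

from .cluster_rules import label_blobs
from .io_formats import AnnotationOutline, DataError

__all__ = ["DiceReport", "reference_mask", "hull_mask", "dice", "evaluate_segmentation"]


@dataclass
class DiceReport:
    dice: float
    true_positive_px: int
    false_positive_px: int
    false_negative_px: int


def reference_mask(outline: AnnotationOutline, shape: tuple[int, int]) -> np.ndarray:
    """Filled annotation polygon, boundary included."""
    verts = np.asarray(outline.vertices, dtype=np.float64)
    if np.unique(np.round(verts, 6), axis=0).shape[0] < 3:
        raise DataError("outline is degenerate: fewer than 3 distinct vertices")
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
    mask[rr, cc] = True
    rr, cc = polygon_perimeter(verts[:, 0], verts[:, 1], shape=shape, clip=True)
    mask[rr, cc] = True
    return mask


def hull_mask(seg: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Filled convex hull of segmented blobs whose centroid lies inside ref.

    A blob belongs to the annotation when its centroid pixel is inside the
    reference mask; the whole blob then contributes to the hull.  Empty
    when no segmented blob qualifies.
    """
    seg = np.asarray(seg, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if seg.shape != ref.shape:
        raise ValueError(f"mask shapes differ: {seg.shape} vs {ref.shape}")
    inside = np.zeros_like(seg)
    for blob in label_blobs(seg).blobs:
        r = min(int(round(blob.centroid[0])), seg.shape[0] - 1)
        c = min(int(round(blob.centroid[1])), seg.shape[1] - 1)
        if ref[r, c]:
            inside[blob.coords[:, 0], blob.coords[:, 1]] = True
    if not inside.any():
        return inside
    return convex_hull_image(inside)


def dice(x: np.ndarray, y: np.ndarray) -> DiceReport:
    """Dice similarity of two aligned binary masks (both-empty -> 1.0)."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    tp = int((x & y).sum())
    fp = int((x & ~y).sum())
    fn = int((~x & y).sum())
    denom = 2 * tp + fp + fn
    score = 1.0 if denom == 0 else 2.0 * tp / denom
    return DiceReport(
        dice=score, true_positive_px=tp, false_positive_px=fp, false_negative_px=fn
    )


def evaluate_segmentation(
    seg: np.ndarray, outline: AnnotationOutline, shape: tuple[int, int] | None = None
) -> DiceReport:
    """Reference mask from the outline, hull of in-annotation MCs, Dice."""
    shape = shape if shape is not None else np.asarray(seg).shape
    ref = reference_mask(outline, shape)
    hull = hull_mask(seg, ref)
    return dice(hull, ref)
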