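"""Microcalcification probability-image generation.

Candidate microcalcification (MC) pixels are isolated by comparing a patch
against an estimate of its smooth tissue background:

1.  The patch is tiled into ``subregion_px`` x ``subregion_px`` sub-regions
    (last row/column truncated at the image edge); the median intensity of
    each sub-region is taken as a robust local background sample and the
    coarse grid of medians is interpolated back to full resolution with a
    bicubic spline.  Bright blobs much smaller than the sub-region size do
    not move the median, so they vanish from the background surface.
2.  Among strictly positive pixels of the difference image
    (patch - background), the top fraction (default 5%) forms a first
    binary image.  The lowest selected difference value is retained as a
    threshold ``t``.  Isolated single pixels are removed and a 3x3 binary
    erosion is applied.  If fewer than 10% of the patch pixels survive
    (a low-contrast patch), every pixel with difference above ``t/2`` is
    added back in: this is **Image A**.
3.  The patch is resampled by bicubic interpolation on a coarse grid
    (default step 3 px, the diameter of the smallest clinically relevant
    MC) and back to full resolution: pixel noise is attenuated while MCs
    survive as local maxima.  A zero-sum 9x9 high-pass kernel (centre 80,
    all 80 off-centre taps -1) then sharpens those maxima and the top 5%
    of the filtered values form **Image B** - bright dots at candidate MC
    positions.
4.  **Image C** is the pixelwise AND of A and B: pixels that stand above
    their local background (A) *and* sit on a compact bright peak (B).

Percentile cut-offs break ties deterministically in raster (row-major)
order so results are identical across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import RectBivariateSpline
from skimage.transform import resize

from .io_formats import ImagePatch

__all__ = [
    "BackgroundModel",
    "DifferenceImage",
    "estimate_background",
    "difference_image",
    "select_top_fraction",
    "cleanup",
    "low_contrast_fallback",
    "bicubic_smooth",
    "highpass_filter",
    "image_b",
    "combine",
    "probability_image",
]

EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class BackgroundModel:
    """Estimated smooth local-background surface for one patch."""

    surface: np.ndarray
    subregion_px: int = 30


@dataclass
class DifferenceImage:
    """Signed patch-minus-background image plus the selection threshold.

    ``threshold_t`` is set by :func:`select_top_fraction`: the lowest
    difference value among the selected top-fraction pixels.  It stays
    ``None`` until a selection has been made (or when no positive pixel
    exists).
    """

    pixels: np.ndarray
    threshold_t: float | None = None


def _tile_centres(n: int, side: int) -> np.ndarray:
    """Centre coordinate of each tile along one axis (last tile truncated)."""
    starts = np.arange(0, n, side)
    ends = np.minimum(starts + side, n)
    return (starts + ends - 1) / 2.0


def _extend_to_edges(centres: np.ndarray, coarse: np.ndarray, n: int, axis: int):
    """Add linearly extrapolated samples at coordinates 0 and n-1.

    The spline evaluator clamps outside the outermost knots, which would
    flatten the border band; extending the coarse grid to the image edges
    keeps e.g. a linear ramp exact all the way to the boundary.
    """
    c = np.moveaxis(coarse, axis, 0)
    cents = centres
    if cents[0] > 0:
        slope = (c[1] - c[0]) / (cents[1] - cents[0])
        first = c[0] - slope * cents[0]
        c = np.concatenate([first[None], c], axis=0)
        cents = np.concatenate([[0.0], cents])
    if cents[-1] < n - 1:
        slope = (c[-1] - c[-2]) / (cents[-1] - cents[-2])
        last = c[-1] + slope * (n - 1 - cents[-1])
        c = np.concatenate([c, last[None]], axis=0)
        cents = np.concatenate([cents, [float(n - 1)]])
    return cents, np.moveaxis(c, 0, axis)


def estimate_background(
    patch: ImagePatch | np.ndarray, subregion_px: int = 30
) -> BackgroundModel:
    """Median-per-subregion background, bicubically interpolated.

    Raises ``ValueError`` when the sub-region does not fit in the image.
    """
    pixels = patch.astype_float() if isinstance(patch, ImagePatch) else np.asarray(
        patch, dtype=np.float64
    )
    rows, cols = pixels.shape
    if subregion_px > rows or subregion_px > cols:
        raise ValueError(
            f"subregion {subregion_px} exceeds image shape {pixels.shape}"
        )
    rc = _tile_centres(rows, subregion_px)
    cc = _tile_centres(cols, subregion_px)
    coarse = np.empty((rc.size, cc.size))
    rstarts = np.arange(0, rows, subregion_px)
    cstarts = np.arange(0, cols, subregion_px)
    for i, r0 in enumerate(rstarts):
        for j, c0 in enumerate(cstarts):
            tile = pixels[r0 : min(r0 + subregion_px, rows),
                          c0 : min(c0 + subregion_px, cols)]
            coarse[i, j] = np.median(tile)
    if rc.size == 1 and cc.size == 1:
        surface = np.full_like(pixels, coarse[0, 0])
    elif rc.size == 1 or cc.size == 1:
        # single tile along one axis: 1-D spline along the other
        along_cols = rc.size == 1
        axis_vals = coarse.ravel()
        axis_cent = cc if along_cols else rc
        n_axis = cols if along_cols else rows
        if axis_vals.size >= 2:
            axis_cent, axis_vals = _extend_to_edges(
                axis_cent, axis_vals, n_axis, axis=0
            )
        k = min(3, axis_vals.size - 1)
        from scipy.interpolate import make_interp_spline

        spl = make_interp_spline(axis_cent, axis_vals, k=k)
        line = spl(np.arange(n_axis))
        surface = np.tile(line, (rows, 1)) if along_cols else np.tile(
            line[:, None], (1, cols)
        )
    else:
        rc2, coarse2 = _extend_to_edges(rc, coarse, rows, axis=0)
        cc2, coarse2 = _extend_to_edges(cc, coarse2, cols, axis=1)
        spl = RectBivariateSpline(
            rc2, cc2, coarse2, kx=min(3, rc2.size - 1), ky=min(3, cc2.size - 1)
        )
        surface = spl(np.arange(rows), np.arange(cols))
    return BackgroundModel(surface=surface, subregion_px=subregion_px)


def difference_image(
    patch: ImagePatch | np.ndarray, background: BackgroundModel
) -> DifferenceImage:
    pixels = patch.astype_float() if isinstance(patch, ImagePatch) else np.asarray(
        patch, dtype=np.float64
    )
    if pixels.shape != background.surface.shape:
        raise ValueError("patch and background shapes differ")
    return DifferenceImage(pixels=pixels - background.surface)


def _top_fraction_mask(values: np.ndarray, candidates: np.ndarray, fraction: float):
    """Select ceil(fraction * len(candidates)) largest values, raster ties.

    ``candidates`` holds flat indices into ``values``; returns (mask, cutoff).
    """
    m = int(np.ceil(fraction * candidates.size))
    cand_vals = values.ravel()[candidates]
    # primary key: descending value; secondary: ascending raster index
    order = np.lexsort((candidates, -cand_vals))
    chosen = candidates[order[:m]]
    mask = np.zeros(values.size, dtype=bool)
    mask[chosen] = True
    return mask.reshape(values.shape), float(values.ravel()[chosen].min())


def select_top_fraction(diff: DifferenceImage, fraction: float = 0.05) -> np.ndarray:
    """Top-fraction mask of strictly positive difference pixels.

    Sets ``diff.threshold_t`` to the lowest selected value.  With no
    positive pixel the mask is empty and the threshold stays undefined.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    pos = np.flatnonzero(diff.pixels.ravel() > 0)
    if pos.size == 0:
        warnings.warn("no positive difference pixels; threshold undefined")
        diff.threshold_t = None
        return np.zeros(diff.pixels.shape, dtype=bool)
    mask, cutoff = _top_fraction_mask(diff.pixels, pos, fraction)
    diff.threshold_t = cutoff
    return mask


def cleanup(mask: np.ndarray) -> np.ndarray:
    """Remove isolated single pixels, then erode with a 3x3 all-ones element.

    A pixel survives the erosion only if its full 3x3 neighbourhood is
    inside the mask (image border counts as background).
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=EIGHT_CONNECTED)
    if n:
        sizes = np.bincount(labels.ravel())
        singles = np.flatnonzero(sizes == 1)
        singles = singles[singles > 0]
        if singles.size:
            mask = mask & ~np.isin(labels, singles)
    return ndi.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))


def low_contrast_fallback(
    mask: np.ndarray, diff: DifferenceImage, min_fraction: float = 0.10
) -> np.ndarray:
    """Image A: rescue low-contrast patches by relaxing the threshold.

    If the mask holds fewer than ``min_fraction`` of all patch pixels, every
    pixel whose difference value exceeds half the recorded selection
    threshold is added.  Otherwise the mask passes through unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() >= min_fraction * mask.size:
        return mask
    if diff.threshold_t is None:
        warnings.warn("selection threshold undefined; fallback skipped")
        return mask
    return mask | (diff.pixels > diff.threshold_t / 2.0)


def bicubic_smooth(
    patch: ImagePatch | np.ndarray, step_px: int = 3
) -> np.ndarray:
    """Bicubic down/up-resampling of the patch on a ``step_px`` grid.

    Decimating with anti-aliasing and interpolating back suppresses pixel
    noise by roughly ``step_px`` while structures of diameter >= ``step_px``
    (the smallest clinically relevant MC is ~0.2 mm, i.e. 3 px at mammographic
    spacings) survive as local maxima.  This is the input of the 9x9
    contrast-enhancement filter of the B-chain.
    """
    pixels = patch.astype_float() if isinstance(patch, ImagePatch) else np.asarray(
        patch, dtype=np.float64
    )
    if step_px < 1:
        raise ValueError("step_px must be >= 1")
    if step_px == 1:
        return pixels.copy()
    rows, cols = pixels.shape
    coarse_shape = (max(4, round(rows / step_px)), max(4, round(cols / step_px)))
    small = resize(pixels, coarse_shape, order=3, anti_aliasing=True)
    return resize(small, (rows, cols), order=3)


def highpass_kernel() -> np.ndarray:
    """9x9 zero-sum high-pass kernel: centre 80, off-centre taps -1."""
    k = -np.ones((9, 9))
    k[4, 4] = 80.0
    return k


def highpass_filter(background: BackgroundModel | np.ndarray) -> np.ndarray:
    """Convolve the background surface with the 9x9 zero-sum kernel.

    Symmetric (reflected) boundary handling; a constant surface maps to an
    all-zero response.
    """
    surface = (
        background.surface
        if isinstance(background, BackgroundModel)
        else np.asarray(background, dtype=np.float64)
    )
    if surface.shape[0] < 9 or surface.shape[1] < 9:
        raise ValueError("surface must be at least 9x9")
    return ndi.convolve(surface, highpass_kernel(), mode="reflect")


def image_b(filtered: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Top-fraction mask over *all* pixels of the high-pass filtered image."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    filtered = np.asarray(filtered, dtype=np.float64)
    all_idx = np.arange(filtered.size)
    mask, _ = _top_fraction_mask(filtered, all_idx, fraction)
    return mask


def combine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Image C: pixelwise AND of Images A and B."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a & b


def probability_image(
    patch: ImagePatch,
    subregion_px: int = 30,
    fraction: float = 0.05,
    fallback_fraction: float = 0.10,
    smooth_step_px: int = 3,
) -> dict:
    """Run the full Image A / B / C chain on one patch.

    Returns a dict with the background model, difference image and the
    three intermediate masks keyed ``image_a``, ``image_b``, ``image_c``.
    """
    bg = estimate_background(patch, subregion_px=subregion_px)
    diff = difference_image(patch, bg)
    raw = select_top_fraction(diff, fraction=fraction)
    cleaned = cleanup(raw)
    a = low_contrast_fallback(cleaned, diff, min_fraction=fallback_fraction)
    b = image_b(
        highpass_filter(bicubic_smooth(patch, step_px=smooth_step_px)),
        fraction=fraction,
    )
    c = combine(a, b)
    return {
        "background": bg,
        "difference": diff,
        "raw_selection": raw,
        "image_a": a,
        "image_b": b,
        "image_c": c,
    }
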