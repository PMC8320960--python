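"""Reading, writing and cropping of mammographic image patches.

The unit of processing throughout the package is the :class:`ImagePatch`:
a 2-D grayscale intensity grid with an attached physical pixel spacing in
micrometres and a nominal bit depth (8, 12 or 16).  Binary masks are plain
boolean numpy arrays aligned with their parent patch; on disk they are
stored as 8-bit PNGs with values 0/255.  Radiologist annotation outlines
are closed polygons given as ordered (row, col) vertices and stored as
2-column CSV files.

Coordinate convention (used package-wide): 0-based (row, col) indices,
origin at the top-left corner, rows increasing downward.  Bounding boxes
are inclusive of both end rows/columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "FormatError",
    "DataError",
    "ImagePatch",
    "AnnotationOutline",
    "read_patch",
    "write_patch",
    "read_mask",
    "write_mask",
    "read_outline",
    "write_outline",
    "crop_roi",
]

VALID_BIT_DEPTHS = (8, 12, 16)


class DataError(ValueError):
    """Input data violates a contract (bad image, bad outline, ...)."""


class FormatError(DataError):
    """A file could not be interpreted as the expected format."""


@dataclass
class ImagePatch:
    """A 2-D grayscale intensity grid with physical pixel spacing.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities, at least 2x2.
    spacing_um
        Pixel spacing in micrometres (> 0); e.g. 70 for a Hologic Selenia
        full-field digital unit, 50 for a Lumisys 200 film scanner.
    bit_depth
        Nominal detector depth; intensities must lie in [0, 2**bit_depth - 1].
    id
        Free-text identifier carried through the pipeline.
    """

    pixels: np.ndarray
    spacing_um: float
    bit_depth: int = 12
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise DataError(f"patch must be 2-D, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise DataError(f"patch must be at least 2x2, got {self.pixels.shape}")
        if not self.spacing_um > 0:
            raise DataError(f"pixel spacing must be positive, got {self.spacing_um}")
        if self.bit_depth not in VALID_BIT_DEPTHS:
            raise DataError(f"bit depth must be one of {VALID_BIT_DEPTHS}")
        lo = float(np.min(self.pixels))
        hi = float(np.max(self.pixels))
        if lo < 0 or hi > self.max_value:
            raise DataError(
                f"intensities [{lo}, {hi}] outside [0, {self.max_value}] "
                f"for bit depth {self.bit_depth}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    def astype_float(self) -> np.ndarray:
        return np.asarray(self.pixels, dtype=np.float64)

    def with_pixels(self, pixels: np.ndarray, id: str | None = None) -> "ImagePatch":
        """A copy of this patch carrying new pixel values."""
        return ImagePatch(
            pixels=pixels,
            spacing_um=self.spacing_um,
            bit_depth=self.bit_depth,
            id=self.id if id is None else id,
        )


@dataclass
class AnnotationOutline:
    """Closed polygon outline in patch coordinates ((row, col) vertices)."""

    vertices: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise DataError("outline vertices must be an (n, 2) array of (row, col)")
        if self.vertices.shape[0] < 3:
            raise DataError("an outline needs at least 3 vertices")

    def bounding_box(self) -> tuple[int, int, int, int]:
        """Inclusive (rowmin, rowmax, colmin, colmax) integer bounding box."""
        r = self.vertices[:, 0]
        c = self.vertices[:, 1]
        return (
            int(math.floor(r.min())),
            int(math.ceil(r.max())),
            int(math.floor(c.min())),
            int(math.ceil(c.max())),
        )


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    hi = int(arr.max()) if arr.size else 0
    return 12 if hi <= 4095 else 16


def read_patch(
    path: str | Path,
    spacing_um: float,
    bit_depth: int | None = None,
    id: str | None = None,
) -> ImagePatch:
    """Read a grayscale PNG/TIFF/PGM image as an :class:`ImagePatch`.

    Intensities are preserved bit-exactly.  ``bit_depth`` defaults to 8 for
    8-bit files and, for 16-bit containers, to 12 when no intensity exceeds
    4095 (the common case for digital mammography exports) and 16 otherwise.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap backend errors
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        raise FormatError(f"{path} is a color image; grayscale input required")
    if arr.ndim != 2 or arr.size == 0:
        raise FormatError(f"{path} is not a non-empty 2-D image")
    depth = bit_depth if bit_depth is not None else _infer_bit_depth(arr)
    return ImagePatch(
        pixels=arr, spacing_um=spacing_um, bit_depth=depth, id=id or path.stem
    )


def write_patch(patch: ImagePatch, path: str | Path) -> None:
    """Write a patch as PNG/TIFF/PGM, choosing uint8 or uint16 by bit depth."""
    dtype = np.uint8 if patch.bit_depth == 8 else np.uint16
    arr = np.asarray(np.rint(patch.pixels), dtype=dtype)
    iio.imwrite(Path(path), arr)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask stored as an image; any non-zero pixel is True."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return np.asarray(arr) > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit PNG with values 0/255."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def read_outline(path: str | Path) -> AnnotationOutline:
    """Read an annotation outline from a 2-column ``row,col`` CSV file."""
    verts = np.loadtxt(Path(path), delimiter=",", skiprows=1, ndmin=2)
    return AnnotationOutline(vertices=verts)


def write_outline(outline: AnnotationOutline, path: str | Path) -> None:
    np.savetxt(
        Path(path),
        outline.vertices,
        delimiter=",",
        header="row,col",
        comments="",
        fmt="%.3f",
    )


def crop_roi(
    patch: ImagePatch, outline: AnnotationOutline, margin_px: int = 0
) -> ImagePatch:
    """Crop the axis-aligned bounding box of an outline, plus a margin.

    The box is inclusive of both end rows/columns, expanded by ``margin_px``
    on every side and clipped to the patch bounds (an oversized margin is
    clipped silently, never an error).
    """
    if margin_px < 0:
        raise ValueError("margin_px must be >= 0")
    rows, cols = patch.shape
    rmin, rmax, cmin, cmax = outline.bounding_box()
    if rmin < 0 or cmin < 0 or rmax >= rows or cmax >= cols:
        raise DataError("outline extends outside the patch bounds")
    r0 = max(0, rmin - margin_px)
    r1 = min(rows - 1, rmax + margin_px)
    c0 = max(0, cmin - margin_px)
    c1 = min(cols - 1, cmax + margin_px)
    return patch.with_pixels(
        patch.pixels[r0 : r1 + 1, c0 : c1 + 1].copy(),
        id=f"{patch.id}_roi" if patch.id else "roi",
    )
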