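"""Wavelet-based contrast enhancement driven by a scalar sharpness index.

The patch is decomposed with a 3-level separable discrete wavelet
transform (Daubechies-4, symmetric extension).  For every level the
log-energies of the horizontal, vertical and diagonal detail sub-bands are
summed into a total log-energy (TLE), and the per-level TLEs are combined
with a fixed weight ``w`` (default 0.10) into the scalar sharpness index

    SSI = w * sum_l TLE_l,      TLE_l = sum_o ln(eps + sum c^2)

Higher SSI means a sharper image.  Enhancement multiplies every detail
coefficient by a gain

    g = 1 + w * max(0, (SSI_ref - SSI) / SSI_ref)

so blurrier patches (SSI far below the reference) receive more boost and
an already-sharp patch is left nearly untouched; the reconstruction is
clipped back into the patch's bit-depth range.  ``SSI_ref`` defaults to
the SSI of a maximal-contrast checkerboard of the same shape and depth -
the sharpest image the grid can hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .io_formats import ImagePatch

__all__ = [
    "WaveletDecomposition",
    "SharpnessProfile",
    "decompose",
    "reconstruct",
    "log_energy",
    "sharpness_profile",
    "ssi",
    "reference_ssi",
    "enhance",
]

LOG_ENERGY_EPS = 1e-12
DEFAULT_WAVELET = "db4"
DEFAULT_MODE = "symmetric"


@dataclass
class WaveletDecomposition:
    """Multi-level separable DWT: approximation + (H, V, D) per level.

    ``details[0]`` is the coarsest level (level L), matching pywt's
    ``wavedec2`` ordering.
    """

    approx: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    shape: tuple[int, int]
    wavelet: str = DEFAULT_WAVELET
    mode: str = DEFAULT_MODE

    @property
    def levels(self) -> int:
        return len(self.details)


@dataclass
class SharpnessProfile:
    """Per-level, per-orientation log-energies and their SSI combination."""

    log_energies: list[tuple[float, float, float]]  # (H, V, D) per level
    tle: list[float]
    weight: float
    ssi: float


def decompose(
    patch: ImagePatch | np.ndarray,
    levels: int = 3,
    wavelet: str = DEFAULT_WAVELET,
) -> WaveletDecomposition:
    """Separable multi-level DWT of a patch."""
    pixels = patch.astype_float() if isinstance(patch, ImagePatch) else np.asarray(
        patch, dtype=np.float64
    )
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if min(pixels.shape) < 2**levels:
        raise ValueError(
            f"image {pixels.shape} too small for {levels} decomposition levels"
        )
    coeffs = pywt.wavedec2(pixels, wavelet, mode=DEFAULT_MODE, level=levels)
    return WaveletDecomposition(
        approx=coeffs[0],
        details=[tuple(d) for d in coeffs[1:]],
        shape=pixels.shape,
        wavelet=wavelet,
    )


def reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse DWT, cropped to the original shape."""
    coeffs = [dec.approx] + [tuple(d) for d in dec.details]
    rec = pywt.waverec2(coeffs, dec.wavelet, mode=dec.mode)
    return rec[: dec.shape[0], : dec.shape[1]]


def log_energy(subband: np.ndarray) -> float:
    """ln(eps + sum of squared coefficients); eps guards the empty band."""
    c = np.asarray(subband, dtype=np.float64)
    return float(np.log(LOG_ENERGY_EPS + np.sum(c * c)))


def sharpness_profile(dec: WaveletDecomposition, weight: float = 0.10
                      ) -> SharpnessProfile:
    energies = [
        (log_energy(h), log_energy(v), log_energy(d)) for (h, v, d) in dec.details
    ]
    tle = [sum(e) for e in energies]
    return SharpnessProfile(
        log_energies=energies, tle=tle, weight=weight, ssi=weight * sum(tle)
    )


def ssi(
    patch: ImagePatch | np.ndarray, levels: int = 3, weight: float = 0.10
) -> float:
    """Scalar sharpness index of an image (higher = sharper)."""
    return sharpness_profile(decompose(patch, levels=levels), weight=weight).ssi


def reference_ssi(
    shape: tuple[int, int], max_value: float, levels: int = 3, weight: float = 0.10
) -> float:
    """SSI of the sharpest image the grid can hold: a full-contrast
    checkerboard at the given shape and intensity ceiling."""
    rr, cc = np.indices(shape)
    board = ((rr + cc) % 2) * float(max_value)
    return ssi(board, levels=levels, weight=weight)


def enhance(
    patch: ImagePatch,
    weight: float = 0.10,
    levels: int = 3,
    ssi_ref: float | None = None,
    wavelet: str = DEFAULT_WAVELET,
) -> ImagePatch:
    """Sharpness-adaptive detail boost.

    ``weight`` in [0, 0.8]: boosts above 0.8 give no further enhancement,
    so larger values are rejected.  ``weight=0`` returns the input (up to
    floating-point round trip through the transform).
    """
    if not 0 <= weight <= 0.8:
        raise ValueError("weight must lie in [0, 0.8]")
    dec = decompose(patch, levels=levels, wavelet=wavelet)
    profile = sharpness_profile(dec, weight=weight if weight > 0 else 0.10)
    if ssi_ref is None:
        ssi_ref = reference_ssi(patch.shape, patch.max_value, levels=levels)
    if ssi_ref > 0:
        gain = 1.0 + weight * max(0.0, (ssi_ref - profile.ssi) / ssi_ref)
    else:
        gain = 1.0
    boosted = WaveletDecomposition(
        approx=dec.approx,
        details=[(h * gain, v * gain, d * gain) for (h, v, d) in dec.details],
        shape=dec.shape,
        wavelet=dec.wavelet,
        mode=dec.mode,
    )
    rec = np.clip(reconstruct(boosted), 0, patch.max_value)
    return patch.with_pixels(rec)
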