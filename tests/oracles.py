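"""Independent brute-force oracles shared by the test suite.

Each function recomputes a quantity by direct enumeration so the
implementation under test is checked against a second, structurally
different route.
"""

from __future__ import annotations

import numpy as np


def erosion_oracle(mask: np.ndarray, k: int, anchored: bool) -> np.ndarray:
    """A pixel survives iff the full kxk window is true.

    ``anchored``: window anchored at the pixel (2x2 case); otherwise
    centred (3x3 case).  Windows leaving the image count as false.
    """
    rows, cols = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    off = 0 if anchored else -(k // 2)
    for i in range(rows):
        for j in range(cols):
            ok = True
            for di in range(k):
                for dj in range(k):
                    r, c = i + off + di, j + off + dj
                    if not (0 <= r < rows and 0 <= c < cols and mask[r, c]):
                        ok = False
            out[i, j] = ok
    return out


def convolve_oracle_interior(surface: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct double-loop convolution, valid on the kernel-interior only."""
    kr, kc = kernel.shape
    hr, hc = kr // 2, kc // 2
    rows, cols = surface.shape
    out = np.full((rows, cols), np.nan)
    for i in range(hr, rows - hr):
        for j in range(hc, cols - hc):
            acc = 0.0
            for di in range(-hr, hr + 1):
                for dj in range(-hc, hc + 1):
                    acc += kernel[hr + di, hc + dj] * surface[i - di, j - dj]
            out[i, j] = acc
    return out


def top_fraction_oracle(values: np.ndarray, candidates_mask: np.ndarray,
                        fraction: float) -> int:
    """Expected selection count: ceil(fraction * number of candidates)."""
    n = int(candidates_mask.sum())
    return int(np.ceil(fraction * n)) if n else 0


def dice_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Dice by per-pixel counting loops."""
    tp = fp = fn = 0
    for a, b in zip(x.ravel(), y.ravel()):
        if a and b:
            tp += 1
        elif a:
            fp += 1
        elif b:
            fn += 1
    return 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)


def glcm_contrast_oracle(quantized: np.ndarray, dr: int, dc: int) -> float:
    """GLCM contrast for one symmetric offset from raw pair counts."""
    rows, cols = quantized.shape
    num = 0.0
    count = 0
    for i in range(rows):
        for j in range(cols):
            r, c = i + dr, j + dc
            if 0 <= r < rows and 0 <= c < cols:
                d = int(quantized[i, j]) - int(quantized[r, c])
                num += 2 * d * d  # symmetric matrix counts both directions
                count += 2
    return num / count if count else 0.0


def auc_pair_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the concordant-pair fraction with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = len(pos) * len(neg)
    acc = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                acc += 1.0
            elif p == n:
                acc += 0.5
    return acc / total


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area by the shoelace formula."""
    v = np.asarray(vertices, dtype=np.float64)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(
        float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    )
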