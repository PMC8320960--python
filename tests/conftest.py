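"""Shared fixtures: deterministic RNGs and small phantom samples."""

from __future__ import annotations

import numpy as np
import pytest

from mcclassify.io_formats import ImagePatch
from mcclassify.synthgen import PhantomSpec, crop_sample, generate_patch


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def flat_patch() -> ImagePatch:
    """Constant 64x64 patch at half range."""
    return ImagePatch(np.full((64, 64), 100.0), spacing_um=70.0, bit_depth=12)


@pytest.fixture
def blob_patch() -> ImagePatch:
    """Flat background 100 with one bright 5x5 blob of 200."""
    pixels = np.full((64, 64), 100.0)
    pixels[30:35, 40:45] = 200.0
    return ImagePatch(pixels, spacing_um=70.0, bit_depth=12)


@pytest.fixture(scope="session")
def phantom_sample():
    """One deterministic benign phantom with ground truth."""
    return generate_patch(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def phantom_roi(phantom_sample):
    """The same phantom cropped to its annotation ROI."""
    return crop_sample(phantom_sample, margin_px=20)
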