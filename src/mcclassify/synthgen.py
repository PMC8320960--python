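"""Synthetic mammographic phantoms with ground truth.

Real microcalcification (MC) patches are small bright granular blobs on
smooth, slowly varying breast tissue.  The generator emulates exactly the
properties the segmentation and classification stages key on:

* background = constant base level + a low-frequency Gaussian random field
  (smooth "tissue" structure) + white Gaussian noise of standard deviation
  ``noise_sigma``;
* blobs = anti-aliased ellipses with an angular radius modulation
  controlled by an ``irregularity`` parameter, additive on top of the
  background with a per-blob contrast drawn from ``contrast_range``
  (expressed as multiples of ``noise_sigma``);
* cluster layout = blob centres placed by a ``scattered``, ``linear`` or
  ``branching`` geometry within a dispersion radius.

Benign and malignant phantoms differ along the axes radiologists use:
benign clusters hold fewer, larger, rounder, more uniformly sized blobs
that are loosely dispersed; malignant clusters hold many small,
pleomorphic (irregular, size-varied) blobs packed tightly.  A scalar
``effect`` in [0, 1] interpolates both class parameterisations towards
their common midpoint, so ``effect=0`` yields two identical distributions
(a null dataset) and ``effect=1`` the fully separated defaults.

Per-sample randomness derives from the master seed through
``np.random.SeedSequence([master_seed, index])`` - a counter-based scheme,
so extending a dataset never reshuffles earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .io_formats import AnnotationOutline, DataError, ImagePatch

__all__ = [
    "BackgroundSpec",
    "BlobPopulationSpec",
    "ClusterSpec",
    "PhantomSpec",
    "PhantomSample",
    "benign_spec",
    "malignant_spec",
    "generate_patch",
    "generate_dataset",
]


@dataclass
class BackgroundSpec:
    base: float = 900.0
    lf_amplitude: float = 40.0  # std of the smooth tissue field
    correlation_length_px: float = 96.0  # ~6.7 mm at 70 um spacing
    noise_sigma: float = 8.0


@dataclass
class BlobPopulationSpec:
    count_range: tuple[int, int] = (8, 14)
    diameter_range_px: tuple[float, float] = (4.0, 8.0)
    contrast_range_sigma: tuple[float, float] = (3.0, 6.0)
    irregularity: float = 0.2  # 0 = smooth ellipse, 1 = strongly lobulated


@dataclass
class ClusterSpec:
    dispersion_radius_px: float = 40.0
    geometry: str = "scattered"  # scattered | linear | branching


@dataclass
class PhantomSpec:
    shape: tuple[int, int] = (256, 256)
    spacing_um: float = 70.0
    bit_depth: int = 12
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    blobs: BlobPopulationSpec = field(default_factory=BlobPopulationSpec)
    cluster: ClusterSpec = field(default_factory=ClusterSpec)
    label: str = "benign"
    seed: int = 0


@dataclass
class BlobRecord:
    centre: tuple[float, float]
    diameter_px: float
    contrast: float
    n_pixels: int


@dataclass
class PhantomSample:
    patch: ImagePatch
    truth_mask: np.ndarray
    outline: AnnotationOutline | None
    label: str
    blobs: list[BlobRecord]


# Class-conditional defaults at full effect.  Malignant clusters: many
# small pleomorphic blobs, tightly packed; benign: fewer large round ones.
_BENIGN = {
    "count_range": (7.0, 11.0),
    "diameter_range_px": (5.0, 8.0),
    "contrast_range_sigma": (3.5, 6.0),
    "irregularity": 0.1,
    "dispersion_radius_px": 48.0,
}
_MALIGNANT = {
    "count_range": (14.0, 22.0),
    "diameter_range_px": (3.0, 5.5),
    "contrast_range_sigma": (3.0, 5.0),
    "irregularity": 0.6,
    "dispersion_radius_px": 30.0,
}


def _interp_class(label: str, effect: float) -> dict:
    if not 0 <= effect <= 1:
        raise ValueError("effect must be in [0, 1]")
    this = _BENIGN if label == "benign" else _MALIGNANT
    out: dict = {}
    for key in this:
        a = np.asarray(this[key], dtype=float)
        b = np.asarray((_MALIGNANT if label == "benign" else _BENIGN)[key], float)
        mid = (a + b) / 2.0
        val = mid + effect * (a - mid)
        out[key] = val
    return out


def class_spec(label: str, effect: float = 1.0, seed: int = 0,
               shape: tuple[int, int] = (256, 256),
               spacing_um: float = 70.0) -> PhantomSpec:
    """Phantom spec for one class at a given class-separation effect size."""
    if label not in ("benign", "malignant"):
        raise ValueError("label must be 'benign' or 'malignant'")
    p = _interp_class(label, effect)
    return PhantomSpec(
        shape=shape,
        spacing_um=spacing_um,
        blobs=BlobPopulationSpec(
            count_range=(int(round(p["count_range"][0])),
                         int(round(p["count_range"][1]))),
            diameter_range_px=tuple(p["diameter_range_px"]),
            contrast_range_sigma=tuple(p["contrast_range_sigma"]),
            irregularity=float(p["irregularity"]),
        ),
        cluster=ClusterSpec(
            dispersion_radius_px=float(p["dispersion_radius_px"]),
            geometry="scattered",
        ),
        label=label,
        seed=seed,
    )


def benign_spec(effect: float = 1.0, seed: int = 0, **kw) -> PhantomSpec:
    return class_spec("benign", effect, seed, **kw)


def malignant_spec(effect: float = 1.0, seed: int = 0, **kw) -> PhantomSpec:
    return class_spec("malignant", effect, seed, **kw)


def _smooth_field(rng: np.random.Generator, shape, corr_len: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    field_ = ndi.gaussian_filter(white, sigma=corr_len / 2.0, mode="reflect")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _blob_centres(rng: np.random.Generator, spec: PhantomSpec, n: int,
                  diameters: np.ndarray) -> np.ndarray:
    """Place n blob centres by the cluster geometry, rejecting overlaps."""
    rows, cols = spec.shape
    radius = spec.cluster.dispersion_radius_px
    margin = 8.0 + diameters.max() / 2.0
    lo_r, hi_r = margin + radius, rows - margin - radius
    lo_c, hi_c = margin + radius, cols - margin - radius
    if lo_r >= hi_r or lo_c >= hi_c:
        centre = np.array([rows / 2.0, cols / 2.0])
    else:
        centre = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
    geometry = spec.cluster.geometry
    if geometry == "linear":
        theta = rng.uniform(0, np.pi)
        axis = np.array([np.sin(theta), np.cos(theta)])
    elif geometry == "branching":
        theta = rng.uniform(0, np.pi)
        dtheta = rng.uniform(np.pi / 4, 3 * np.pi / 4)
        arms = [np.array([np.sin(t), np.cos(t)]) for t in (theta, theta + dtheta)]
    elif geometry != "scattered":
        raise ValueError(f"unknown cluster geometry {geometry!r}")

    placed: list[np.ndarray] = []
    for i in range(n):
        ok = False
        for _ in range(400):
            if geometry == "scattered":
                r = radius * np.sqrt(rng.uniform())
                a = rng.uniform(0, 2 * np.pi)
                cand = centre + r * np.array([np.sin(a), np.cos(a)])
            elif geometry == "linear":
                t = rng.uniform(-radius, radius)
                jit = rng.normal(0, radius / 6.0)
                perp = np.array([axis[1], -axis[0]])
                cand = centre + t * axis + jit * perp
            else:  # branching
                arm = arms[int(rng.integers(2))]
                t = rng.uniform(0, radius)
                jit = rng.normal(0, radius / 8.0)
                perp = np.array([arm[1], -arm[0]])
                cand = centre + t * arm + jit * perp
            if not (margin <= cand[0] < rows - margin
                    and margin <= cand[1] < cols - margin):
                continue
            sep_ok = all(
                np.hypot(*(cand - p)) >= (diameters[i] + diameters[j]) / 2.0 + 3.0
                for j, p in enumerate(placed)
            )
            if sep_ok:
                placed.append(cand)
                ok = True
                break
        if not ok:
            raise DataError(
                f"could not place blob {i + 1}/{n} without overlap; "
                "reduce count or enlarge the patch"
            )
    return np.array(placed)


def _render_blob(rng: np.random.Generator, canvas: np.ndarray,
                 truth: np.ndarray, centre: np.ndarray, diameter: float,
                 contrast: float, irregularity: float) -> int:
    """Additively draw one anti-aliased deformed ellipse; returns pixel count."""
    rows, cols = canvas.shape
    rad = diameter / 2.0
    aspect = 1.0 + irregularity * rng.uniform(0.0, 1.0)
    a = rad * np.sqrt(aspect)
    b = rad / np.sqrt(aspect)
    theta = rng.uniform(0, np.pi)
    m3, m5 = irregularity * 0.35 * rng.uniform(size=2)
    p3, p5 = rng.uniform(0, 2 * np.pi, size=2)
    half = int(np.ceil(a * (1 + 0.5 * irregularity))) + 2
    r0 = int(np.floor(centre[0]))
    c0 = int(np.floor(centre[1]))
    rs = slice(max(0, r0 - half), min(rows, r0 + half + 1))
    cs = slice(max(0, c0 - half), min(cols, c0 + half + 1))
    rr, cc = np.mgrid[rs, cs]
    dy = rr - centre[0]
    dx = cc - centre[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    phi = np.arctan2(v, u)
    mod = 1.0 + m3 * np.sin(3 * phi + p3) + m5 * np.sin(5 * phi + p5)
    rho_eff = rho / np.maximum(mod, 0.3)
    alpha = np.clip((1.0 - rho_eff) * max(b, 1.0) + 0.5, 0.0, 1.0)
    canvas[rs, cs] += contrast * alpha
    core = alpha >= 0.5
    truth[rs, cs] |= core
    return int(core.sum())


def _outline_from_truth(truth: np.ndarray, dilate_px: int = 3
                        ) -> AnnotationOutline | None:
    """Annotation outline: convex hull of the dilated truth mask."""
    if not truth.any():
        return None
    dil = ndi.binary_dilation(truth, iterations=dilate_px)
    pts = np.argwhere(dil)
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices].astype(float)
    except QhullError:
        rmin, cmin = pts.min(axis=0)
        rmax, cmax = pts.max(axis=0)
        verts = np.array([[rmin, cmin], [rmin, cmax], [rmax, cmax], [rmax, cmin]],
                         dtype=float)
    return AnnotationOutline(vertices=verts)


def generate_patch(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom patch with pixel-level ground truth.

    Identical spec (including seed) always produces identical output.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    rows, cols = spec.shape
    bg = spec.background
    canvas = (
        bg.base
        + bg.lf_amplitude * _smooth_field(rng, spec.shape, bg.correlation_length_px)
        + bg.noise_sigma * rng.standard_normal(spec.shape)
    )
    truth = np.zeros(spec.shape, dtype=bool)
    records: list[BlobRecord] = []
    lo, hi = spec.blobs.count_range
    n = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
    if n > 0:
        diameters = rng.uniform(*spec.blobs.diameter_range_px, size=n)
        contrasts = bg.noise_sigma * rng.uniform(
            *spec.blobs.contrast_range_sigma, size=n
        )
        centres = _blob_centres(rng, spec, n, diameters)
        for i in range(n):
            npx = _render_blob(
                rng, canvas, truth, centres[i], diameters[i], contrasts[i],
                spec.blobs.irregularity,
            )
            records.append(
                BlobRecord(
                    centre=(float(centres[i][0]), float(centres[i][1])),
                    diameter_px=float(diameters[i]),
                    contrast=float(contrasts[i]),
                    n_pixels=npx,
                )
            )
    max_val = 2**spec.bit_depth - 1
    pixels = np.clip(canvas, 0, max_val)
    patch = ImagePatch(
        pixels=pixels,
        spacing_um=spec.spacing_um,
        bit_depth=spec.bit_depth,
        id=f"phantom_{spec.label}_{spec.seed}",
    )
    return PhantomSample(
        patch=patch,
        truth_mask=truth,
        outline=_outline_from_truth(truth),
        label=spec.label,
        blobs=records,
    )


def crop_sample(sample: PhantomSample, margin_px: int = 20) -> PhantomSample:
    """Annotation-centred ROI view of a phantom, truth and outline shifted.

    Mirrors what the pipeline does with real data: crop the region around
    the radiologist outline before segmentation.
    """
    if sample.outline is None:
        return sample
    from .io_formats import crop_roi  # local import avoids cycle at import time

    rmin, _, cmin, _ = sample.outline.bounding_box()
    roi = crop_roi(sample.patch, sample.outline, margin_px=margin_px)
    r0 = max(0, rmin - margin_px)
    c0 = max(0, cmin - margin_px)
    truth = sample.truth_mask[r0 : r0 + roi.shape[0], c0 : c0 + roi.shape[1]]
    outline = AnnotationOutline(sample.outline.vertices - np.array([r0, c0]))
    return PhantomSample(
        patch=roi,
        truth_mask=truth,
        outline=outline,
        label=sample.label,
        blobs=sample.blobs,
    )


def sample_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), int(index)])


def generate_dataset(
    n_benign: int,
    n_malignant: int,
    effect: float = 1.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    spacing_um: float = 70.0,
) -> list[PhantomSample]:
    """Benign-then-malignant list of phantoms with per-index derived seeds."""
    samples: list[PhantomSample] = []
    labels = ["benign"] * n_benign + ["malignant"] * n_malignant
    for i, label in enumerate(labels):
        sub = sample_seed(seed, i)
        spec = class_spec(label, effect=effect,
                          seed=int(sub.generate_state(1)[0] % (2**31)),
                          shape=shape, spacing_um=spacing_um)
        sample = generate_patch(spec)
        sample.patch.id = f"phantom_{label}_{i:04d}"
        samples.append(sample)
    return samples
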