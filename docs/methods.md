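# Methods

This note records the models and procedures `mcclassify` implements, the
parameters that matter, the choices made where the design was open, and
what the synthetic phantoms do and do not establish.

## Processing model

The unit of processing is a 2-D grayscale patch with a physical pixel
spacing (µm) and a nominal bit depth (8/12/16). All coordinates are
0-based `(row, col)` with the origin at the top-left and inclusive
bounding boxes; a single convention is used across every module to avoid
off-by-one drift. When a radiologist outline is available, the pipeline
crops the annotation-centred ROI (bounding box plus a configurable
margin, default 20 px) before segmentation: the percentile budgets of the
segmentation chain (5% selections, 10% fallback) are calibrated to a
patch in which the cluster occupies a non-negligible area fraction, and
running them on a whole mammogram-scale image starves them.

## Enhancement

A 3-level separable DWT (Daubechies-4, symmetric extension — a standard
separable choice; the family is swappable) yields detail sub-bands
H/V/D per level. Sharpness is summarised by per-level total log-energies
`TLE_ℓ = Σ_o ln(ε + Σ c²)` (ε = 1e−12 guards empty bands) combined with a
fixed per-level weight w = 0.10 into `SSI = w·Σ_ℓ TLE_ℓ`; higher SSI
means a sharper image. Enhancement multiplies all detail coefficients by

    g = 1 + w · max(0, (SSI_ref − SSI) / SSI_ref),

so an already-sharp patch (SSI ≥ SSI_ref) passes through unchanged and a
blurry one is boosted by up to a factor 1 + w. `SSI_ref` defaults to the
SSI of a full-contrast checkerboard of the same shape and bit depth — the
sharpest image the grid can represent — and is configurable. The exact
gain law is this package's instantiation; the binding contracts are the
property tests: blob contrast increases, is monotone in the weight, and
w = 0 is the identity. Weights above 0.8 are rejected (larger boosts give
no further enhancement).

## Segmentation (Images A, B, C)

**Background estimation.** The patch is tiled into `subregion_px` ×
`subregion_px` tiles (default 30, trading off over- vs under-segmentation;
the last row/column is truncated at the image edge). Each tile is
summarised by its **median** — robust, so bright MCs much smaller than
the tile do not move it — and the coarse grid is interpolated back to
full resolution with a bicubic spline. Because the spline evaluator
clamps outside its outermost knots, the coarse grid is first extended to
the image edges by linear extrapolation; this keeps e.g. a linear
intensity ramp exact to the boundary (verified to 1% of range in tests).

**Image A.** Among strictly positive pixels of patch − background, the
`⌈0.05·n_pos⌉` largest are selected (ties broken in raster order, so the
result is platform-independent); the lowest selected value is recorded as
threshold *t*. Isolated single pixels are removed and a 3×3 all-ones
erosion applied. If fewer than 10% of the patch pixels survive — the
typical case for sparse MC content and always the case for low-contrast
patches — every pixel with difference above *t*/2 is added back.

**Image B.** A zero-sum 9×9 kernel (centre 80, all 80 off-centre taps −1,
symmetric boundary handling) is convolved with a bicubic down/up
resampling of the patch (grid step 3 px — the diameter of the smallest
clinically relevant MC, ≈0.2 mm at mammographic spacings — so pixel noise
is attenuated while every relevant MC survives as a local maximum). The
top 5% of the filtered values form Image B: compact bright peaks at
candidate MC positions. Applying the same filter to the *median-based
background surface* instead cannot work — that surface is blob-free by
construction, so its high-pass energy reflects tissue-field curvature and
spline wiggles rather than MCs; with that wiring the full chain's
planted-blob recall collapses to ≈4%. The filter input must retain the
calcifications, which is what the resampled-patch reading provides
(recall ≈99% under the same conditions).

**Image C** is A AND B: pixels that stand above their local background
*and* sit on a compact bright peak.

**Cluster rules.** Components of 1–2 pixels are removed as artifacts,
then a 2×2 all-ones erosion is applied. Even-sized kernels have no
centre; the anchor is fixed at the top-left kernel cell
(`out[i,j] = m[i,j]&m[i+1,j]&m[i,j+1]&m[i+1,j+1]`), documented and
oracle-tested. Surviving 8-connected components are blobs; the patch is
tiled into 1 cm² blocks from the top-left (side `round(10000/spacing_um)`
px: 143 at 70 µm, 200 at 50 µm; last row/column truncated), each blob is
assigned to the block containing its centroid (whole-object counting;
boundary-straddling objects are not split), and all blobs of any block
with fewer than `min_per_block` (default 3 — "no fewer than three MCs per
cm²") are erased. A non-clinical block side (e.g. 100 px) can be forced
for sensitivity analyses. The block grid is fixed, not sliding; a cluster
straddling a block boundary can lose the minority side.

## Segmentation evaluation

The reference mask is the filled annotation polygon, boundary pixels
included (a boundary-inclusive raster of a lattice polygon holds
A + P/2 + 1 points, which the tests account for via Pick's theorem).
Segmented blobs whose centroid lies inside the reference contribute their
full pixel set to a convex hull (filled), and hull vs reference is scored
by Dice = 2|X∩Y|/(|X|+|Y|). Two empty masks score 1 (agreement on
absence); this degenerate case is a package definition.

## The 51-feature descriptor

The registry holds exactly 51 named features, 17 per category (size,
shape, texture), in a fixed order exported by `registry_table()`. It
includes the clinically named quantities — summation of per-MC mean
intensities (density proxy), variance of the MC-centroid distances from
the cluster centroid (distribution), cluster convex-hull area, mean MC
perimeter, cluster area, mean MC size — and fills the remaining slots
with standard aggregates (mean/std/min/max over blobs) of per-blob
geometry, cluster-level moments, first-order intensity statistics and
GLCM statistics. Conventions:

* *Perimeter* is the integer crack length (each exposed pixel edge counts
  1) — exactly reproducible. *Circularity* `4πA/P²` instead uses the
  Crofton-style perimeter estimate, because the crack length of any
  convex shape equals twice its bounding width+height and would score a
  disk ≈0.56 rather than ≈1.
* Cluster hull area/perimeter come from the convex hull of blob pixel
  *centres* (so four corner pixels of a 100×100 square give the shoelace
  area 99² = 9801); degenerate point sets (collinear, <3 points) fall
  back to the plain pixel area and crack perimeter.
* Degenerate blobs stay finite: a single pixel has eccentricity 0,
  elongation 1, circularity 1; elongation divides the major axis by
  max(minor axis, 1 px).
* GLCM features use 32 gray levels re-quantised over the observed
  min–max of the cluster bounding box (bit-depth independent and
  invariant to affine intensity rescaling), distance 1, the four
  8-neighbour offsets, symmetric and normalised; entropy is in bits.
* "Variance of the standard deviation of the distances" is implemented
  as the variance of the per-blob centroid-distance values — the grouping
  behind the nested phrasing is not further specified anywhere, and this
  is the reading that matches the "MC distribution" interpretation.

## Feature selection

CFS with Hall's merit `k·r̄_cf / √(k + k(k−1)·r̄_ff)`. Correlations are
point-biserial (feature vs binary class) and Pearson (feature–feature),
in absolute value — a continuous-data simplification of the discretised
symmetric-uncertainty variant, isolated behind `CorrelationTables` so the
measure can be swapped. The empty set has merit 0; constant features get
zero correlations. Best-first search is bidirectional (single additions
*and* deletions), expands the best open node, and stops after
`stale_limit = 5` (the customary default) consecutive non-improving
expansions; ties break by feature order, so the search is deterministic.
On ≤12-feature problems it reproduces the exhaustive-enumeration optimum
on all tested random instances. The α∩β protocol intersects the
selections from unenhanced and enhanced feature tables (features robust
to the enhancement perturbation); an empty intersection falls back to α
with a warning. In `stability_check`, selection runs only on each fold's
training portion. In the end-to-end driver the α∩β selection is computed
once on the full tables for reporting and the classifiers are
cross-validated on that subset; the per-fold stability check (identical
subsets in every fold under the strong-signal generator, and under a fold
count of 9 vs 10) is the evidence that this shortcut does not leak
materially at the effect sizes used.

## Classification

Nine base learners with the printed hyper-parameters and otherwise
library defaults: kNN (k = 5), MLP (one hidden layer of
⌈(n_features + 2)/2⌉ units, SGD with learning rate 0.3 and momentum 0.2,
validation-based stopping after 20 non-improving epochs, 300 epochs
maximum; on training folds too small for a stratified validation split
the stopping is skipped), decision tree, random forest, Gaussian naive
Bayes, and four SVMs (RBF, sigmoid, linear, polynomial) whose decision
values are mapped to votes by sign. Features are z-scored inside the
kNN/SVM/MLP pipelines, fitted on training folds only.

The **ensemble** estimate is the malignant-vote fraction of the nine
learners (8/9 → 89%), thresholded at ½ (a tie is impossible with an odd
count). **Stacked generalization** trains the meta-classifier (Gaussian
naive Bayes by default, AdaBoost optionally) on the base learners'
out-of-fold *binary predictions* from an internal stratified 5-fold split
of the training data — the out-of-fold construction is the leakage guard;
resubstitution predictions would let the meta-learner overfit the base
learners' training error. The AUC score for stacking is the
meta-learner's malignancy probability.

Evaluation: stratified k-fold (default 10) where the seed shuffles the
fold assignment; each observation is tested exactly once per seed run
(asserted at run time), and accuracy (%) and A_z are reported as
mean ± std over seed runs 1..10. LOOCV is a single deterministic run of
n fits. A_z is computed as the trapezoidal ROC area, identical to the
normalised Mann–Whitney rank-sum statistic (concordant-pair fraction with
half credit for ties) — the standard identity, oracle-tested; classes
smaller than the fold count reduce the fold count with a warning.

## Synthetic phantoms

Each phantom is base level 900 (12-bit scale) + a Gaussian random field
of amplitude 40 smoothed to a correlation length of 96 px (≈6.7 mm at
70 µm — parenchymal-density scale) + white noise of σ = 8, plus planted
blobs: anti-aliased ellipses with an angular radius modulation controlled
by an `irregularity` parameter, contrasts drawn in units of σ. The
correlation length matters: much shorter tissue fields defeat the
30-px-tile spline fit, and the misfit residuals both steal the A-chain's
top-5% budget and create correlated false-positive clumps.

Class morphology at full effect — benign: 7–11 blobs of 5–8 px diameter,
contrast 3.5–6σ, irregularity 0.1, dispersion radius 48 px; malignant:
14–22 blobs of 3–5.5 px, contrast 3–5σ, irregularity 0.6, dispersion
30 px. These axes were chosen so that the clinically named discriminative
features (cluster area, blob size, density, distance variance) are the
true signal carriers, which is what makes feature-selection recovery
meaningful. The scalar `effect ∈ [0, 1]` interpolates both class
parameterisations linearly toward their common midpoint; `effect = 0`
yields two identical distributions (a null dataset on which accuracy must
sit at chance). Per-sample seeds derive from the master seed via
`SeedSequence([master, index])` — counter-based, so extending a dataset
never changes earlier samples, and output is platform-reproducible.

What the phantoms do **not** emulate: X-ray physics, scatter, detector
MTF, anatomic texture (ducts, vessels, masses), overlapping tissue
structures, and annotation noise. Passing the recovery suites therefore
shows the chain is internally correct and sensitive to the intended
morphology axes at realistic contrast — not that clinical-database
accuracy would match; published per-database figures depend on data this
package deliberately does not ship.

## Problem sizes and numerical choices

The recovery suites use 50 phantoms (segmentation: recall, false
positives, hull Dice) and 100+100 phantoms with seeds 1..10
(classification), with a 3-seed run for the null — sizes at which the
reported means are stable to well under the acceptance margins.
Percentile ties break in raster order; erosion at the image border treats
outside pixels as background; all feature values are forced finite
(degenerate statistics impute 0); GLCM correlation of a constant region
is 1 by the library's convention. Everything downstream of a fixed seed —
generator, segmentation, features, selection, CV — is bit-reproducible,
and the pipeline manifest records the config hash and package version.

## Known limitations

* The fixed block grid loses cluster fragments straddling block
  boundaries (a sliding-window rule would avoid this at significant
  cost).
* The low-contrast fallback keys on the difference image (the threshold
  is a difference-image value); patches whose background estimate is
  biased can admit extra pixels.
* CFS with point-biserial correlations sees only linear feature–class
  association; a feature informative purely through interaction terms
  would be missed.
* Unsegmentable patches (no blobs after the cluster rule) are excluded
  from classification and counted — single isolated MCs cannot be
  characterised by cluster morphology at all.
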