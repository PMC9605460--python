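# Methods

## Pipeline overview

The package maps a binary vessel mask to an ordinal severity grade in
four stages:

1. **Preprocessing** — topology-preserving iterative thinning
   (Zhang–Suen, via scikit-image) produces a 1-px skeleton under
   8-connectivity; endpoint-terminated twigs shorter than
   `max_spur_length` (default 5 px) that terminate at a branch point
   are pruned iteratively to a fixed point; branch pixels (≥ 3 skeleton
   neighbors) are merged into 8-connected clusters, dilated by one
   step, and cut out of the skeleton; the remaining components are
   traced into ordered segments. Fragments lying entirely within
   `junction_radius` (default 2 px) of a branch representative
   ("L-shaped" junction artifacts) and fragments shorter than
   `min_segment_points` (default 5) are discarded. The extraction
   keeps exact pixel accounting: segment pixels + junction pixels +
   discarded pixels partition the skeleton foreground.
2. **Metrics** — each segment's ordered points are resampled at uniform
   arc-length spacing, optionally Gaussian-smoothed, assigned a signed
   curvature by central finite differences, and reduced to the fourteen
   tortuosity measures plus the curvature summary statistics.
3. **Features** — segment records are assembled into a segment-level
   table (one row per vessel fragment) and aggregated per image into
   count + avg/min/max of each measure. Degenerate values (e.g. ratios
   over a zero chord) are explicit missing values with a flag, never
   silent zeros, and are excluded from aggregates.
4. **Classification** — an entropy decision tree with cost-complexity
   pruning, a rotation forest (per-tree PCA rotation of random feature
   subsets), or a random forest realized as bagged extremely randomized
   trees (bootstrap resampling plus randomized split thresholds).
   Stratified 10-fold cross-validation pools out-of-fold predictions
   into one report: accuracy, Cohen's κ, the 4×4 confusion matrix,
   per-class TPR/FPR/precision/F-score/ROC-AUC, and RMSE/MAE computed
   on predicted class-probability vectors against one-hot truth,
   averaged over samples and classes.

## Discrete curvature estimation

Resampling uses `n = round(L/step) + 1` exactly evenly spaced positions
on `[0, L]`, so the actual spacing is as close to `step` as possible
while the endpoints are preserved. Two properties motivated this over
a fixed-step grid with a short final interval: the turn-angle metric
requires exactly even spacing, and the sample grid is symmetric under
traversal reversal, which makes every metric reversal-invariant to
floating-point precision.

Curvature comes from central finite differences of the resampled
coordinates (one-sided at the boundary samples). Subsegments for the
distance factor and the tortuosity density are maximal runs of constant
curvature sign; the split points are linear interpolations of the zero
crossing between the bracketing samples — again so that the subdivision
is reversal-symmetric. A sign change is only counted (for inflections
and subdivision) when both sides exceed `eps_kappa` in magnitude.

The record's arc length is measured on the resampled (and smoothed)
centerline rather than on the raw pixel chain. For exact point lists
with smoothing off the two agree to float precision; on rasters this
choice removes the staircase length bias, which would otherwise push
the measured DM of an oblique straight vessel to ≈ 1.08.

### Raster-specific corrections

A thinned skeleton carries ±0.3–0.5 px quantization jitter and, on
bands of constant curvature, a low-frequency moiré wobble against the
pixel grid. Three measures keep the curvature-based metrics accurate
on raster input (none is applied to exact point lists, where
`smoothing_sigma = 0`):

* **Gaussian coordinate smoothing** (default σ = 2.5 px at the default
  1-px-spacing scale; σ should be scaled up with the vessel scale of
  the image, e.g. σ ≈ 7 px for curvature radii of 30–50 px). The curve
  is extended by quadratic extrapolation before filtering so that
  straight segments stay exactly straight and curved ends are not
  flattened toward their secant.
* **Curvature deconvolution.** Gaussian smoothing along the arc shrinks
  a circle of radius r by `exp(−σ²/(2r²))`, inflating measured squared
  curvature by `exp(σ²C²)`. The per-point correction
  `C ← C·exp(−σ²C²/2)` inverts this exactly for constant curvature and
  to first order for slowly varying curvature.
* **End-window extrapolation.** Thinning terminates a vessel cap in a
  short axis- or diagonal-aligned run, so the skeleton's end tangents
  are quantized to the grid (errors of ~2–3° per end, occasionally
  more). The curvature inside ~1.75 σ of each end is therefore
  replaced by a linear fit to the adjacent interior, which removes the
  spurious turning the corrupted tangents would inject into τ₂…τ₇.

Measured on rasterized thickness-3 fixtures at vessel scale (curvature
radii 26–50 px, two sub-pixel grid phases), every metric then agrees
with its closed form within 5%, and within 2% on exact point lists at
0.2-px sampling. Residual noise floors remain for quantities whose
true value is zero: a straight 300-px raster line shows up to
~0.5°/px of SOAM, ~0.01 of τ₃ and ~0.075 rad of |τ₂|. Curvature radii
below ~8 px or above ~(canvas scale)/3 are outside the estimator's
reliable band at thickness 3; DM, arc, chord and the inflection count
are robust everywhere.

## Defaults and units

| parameter | default | units | role |
|---|---|---|---|
| `min_segment_points` | 5 | px | shorter fragments carry no reliable curvature |
| `max_spur_length` | 5 | px | spur-pruning bound, applied to a fixed point |
| `junction_radius` | 2 | px | L-artifact rejection radius around branch clusters |
| `resample_step` | 2 | px | arc-length spacing of the uniform resampling |
| `smoothing_sigma` | 2.5 | px | raster jitter suppression; 0 for point lists |
| `eps_kappa` | 0.03 | 1/px | sign-change guard (10⁻³ for point lists) |
| `n_trees` | 105 | — | ensemble size |
| `stopping_rounds / metric / tolerance` | 3 / RMSE / 5·10⁻⁴ | — | early-stopping rule, 500 trees maximum |
| `n_folds` | 10 | — | stratified cross-validation |

The early-stopping monitor stops after evaluation *j* as soon as the
improvement across the last `stopping_rounds` evaluations,
`series[j−rounds] − series[j−1]`, falls below the tolerance; a flat
series stops after exactly `stopping_rounds` evaluations and a series
that keeps improving by more than the tolerance per step never stops
before the tree cap.

## Severity classifiers

"Decision tree" is scikit-learn's CART with the entropy criterion and
cost-complexity pruning (α = 10⁻³) — an information-gain tree in the
C4.5 family rather than a line-for-line C4.5 port. The "random forest"
is `ExtraTreesClassifier` with bootstrap resampling, i.e. bagging plus
randomized split-threshold selection, voting by averaged class
probabilities with ties broken toward the lower (milder) grade. The
rotation forest is implemented in-package: for every tree the features
are partitioned at random into subsets of ~3, each subset is rotated by
a PCA fitted on a bootstrap sample of 75% of the rows, and a CART tree
is trained on the block-rotated data. Multiclass RMSE/MAE are defined
on probability-vs-one-hot residuals, the convention of
distributed-ML frameworks; they are reported alongside accuracy and κ
rather than asserted against each other.

## Synthetic data

The generator serves two distinct purposes.

**Oracle curves** (lines, circular arcs, sinusoids, spirals, the
two-semicircle "S") come with closed-form or quadrature reference
values for arc, chord, DM, total curvature and inflection count; they
are the ground truth for the estimator tests and can be rasterized at a
chosen thickness to exercise the full mask pipeline.

**Labeled severity datasets** emulate the ordinal grading task: each
image holds 12 sinusoidal "vessel" segments with span uniform on
80–160 px and amplitude/cycle-count drawn from truncated normals whose
means rise with grade (amplitude 1/3/6/10 px, cycles 0.5/1.5/2.5/4 for
grades 1–4; sd = 25% of the mean). This ties the grade directly to
curvature magnitude — the clinical notion of twistedness — and makes
the grade-conditional DM/ICM/SOAM distributions strictly ordered.
What the generator does **not** emulate: vessel width variation and
branching geometry of real vasculature, segmentation errors (gaps,
merged vessels), illumination artifacts, optic disc and macula, or
inter-grader label noise. A classifier at accuracy ≈ 1 on this ladder
therefore demonstrates that the feature pipeline preserves and the
models recover the ordinal tortuosity signal — not that real fundus
images are graded at that accuracy; published figures on expert-labeled
clinical data are in the 91–99% range and require that data.

Problem sizes in the tests and the acceptance script (400 images for
cross-validation, 50 random trees for the conservation check, fixtures
of a few hundred pixels) were chosen as the smallest sizes at which the
statistical checks are stable; all runs complete in seconds on one CPU.

## Degenerate inputs and numerical choices

Closed or near-closed segments (chord ≈ 0) flag every chord-normalized
metric as missing rather than infinite. Segments with fewer than five
resampled points flag the curvature block. Zero-chord subsegments are
skipped with a warning inside DF/TD. Aggregation sorts values before
averaging so image records are exactly permutation-invariant; CSV
writers use `%.17g` and readers round-trip parsing, so tables
round-trip bit-identically. Tracing starts at the lexicographically
smallest delimiter with a clockwise-from-north neighbor scan, making
segment point order deterministic; all stochastic components (the
generator, bootstrap, fold shuffling) are driven by explicit seeds.

## Known limitations

* Raster curvature metrology degrades outside the documented band;
  sub-pixel centerline refinement from the mask (rather than the binary
  skeleton) would be the next step in accuracy.
* Exact 90°-rotation equivariance holds for everything downstream of
  the skeleton; the thinning step itself (as in standard scan-order
  implementations) can differ by a few pixels between a rotated and an
  unrotated mask.
* The rotation forest is a compact reference implementation, not tuned
  for large feature spaces.
* Severity grading is only as good as the input mask; vessel
  segmentation from color fundus images is out of scope.
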