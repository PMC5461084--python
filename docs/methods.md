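# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `svddmap`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The one-class model

SVDD describes the target class by the smallest hypersphere enclosing its
training spectra in RBF-kernel feature space. With `K(x,y) =
exp(−‖x−y‖²/s²)` (so `K(x,x) = 1`), the dual problem reduces to

    min  αᵀKα   s.t.  Σαᵢ = 1,  0 ≤ αᵢ ≤ C.

Feasibility requires `C ≥ 1/n`; `fit_svdd` rejects smaller C with an
explicit error, and the annealer resamples such candidates (with the
default 120-pixel training set the search box `C ≥ 0.01 > 1/120` is always
feasible). A point z is accepted iff its squared kernel distance to the
centre is at most R², boundary inclusive — training support vectors that
sit exactly on the sphere must be accepted.

Interpretation of the two controls: each bounded support vector carries
weight C, so at most `⌊1/C⌋` training points can be pushed outside the
sphere — C = 1 encloses everything, C → 1/n approaches the centroid
description. s sets the length scale on which spectra look similar: small s
wraps each training point tightly (fragmented boundary), large s tends to a
single near-spherical boundary in input space.

### Feature scaling

Spectra are z-scored per band with statistics from the training set, and
the same transform is applied at prediction. The (0.01, 20) kernel-width
box is only meaningful on a fixed scale; without standardization it would
be unit-dependent (DN vs reflectance). This is a package convention, not
part of the mathematical model; `fit_svdd(..., standardize=False)` turns it
off (used by the closed-form unit tests).

### The SMO solver

The dual is solved by most-violating-pair sequential minimal optimization:
repeatedly transfer weight from the active coordinate with the largest
gradient to the one with the smallest, with the exact 1-D step
`δ = (gⱼ−gᵢ)/(2(Kᵢᵢ+Kⱼⱼ−2Kᵢⱼ))` clipped to the box, until the KKT gap falls
below 1e−8. Support vectors are identified with `α_tol = 1e−6`, but the
model retains every coordinate with α > 0 so that decision distances,
R² and the Σα = 1 invariant are mutually consistent to solver precision.
R² is the maximum squared distance over *unbounded* support vectors (they
are equidistant at the exact optimum; the maximum guarantees none of them
is rejected by the fitted model). If every support vector is at its bound
(degenerate, e.g. C ≈ 1/n), R² falls back to the mean over bounded ones.
The test suite checks the solver against scipy's SLSQP on random instances
(objective gap ≤ 1e−6) and against the ν-SVM equivalence
`ν = 1/(nC)` of scikit-learn's OneClassSVM.

## Edge training set

Two sources, kept disjoint:

- **Mixed pixels** (default 60): target-labeled pixels with a non-target
  8-neighbour. Pixels whose only "non-target" neighbour is the image border
  are used only as a fallback, since they carry no mixed spectrum. The
  subsample is taken as every k-th pixel in boundary-scan order with a
  seeded random phase, which spreads samples along the boundary instead of
  clumping.
- **Corner pixels** (default 60): convex-hull vertices of the remaining
  (non-boundary) target pixels in the MNF1–MNF2 plane. Restricting
  candidacy to non-boundary pixels matters: in a scene with significant
  mixing, the hull of *all* target-labeled pixels consists of deep mixture
  pixels, and a sphere forced to enclose them inflates over neighbouring
  classes. Hull shortfalls are handled by peeling (remove vertices,
  recompute); surpluses by ranking vertices on distance from the candidate
  centroid and truncating.

The default 120 pixels satisfies the 30p rule of thumb for p = 4 bands; a
warning is raised when a caller goes below it.

MNF here is the generalized eigendecomposition `Σ_total v = λ Σ_noise v`
with the noise covariance estimated by horizontal shift differences
(difference of each pixel with its right neighbour, covariance halved) — a
standard, parameter-free estimator. The transform whitens the noise
(`WᵀΣ_noise W = I`) and orders components by decreasing SNR-like
eigenvalue. Near-singular noise covariances are ridge-regularized with a
warning; constant images are rejected.

## Window-based validation

The validation set is the union of w×w windows centred on each training
pixel, minus all training coordinates, deduplicated, clipped at the image
edge, and labeled target/outlier from the reference map (machine-readable
labels replace the visual interpretation a human operator would do on real
imagery). Pixels of classes listed in `exclude_codes` are dropped — the
untrained-class experiment. Because training pixels concentrate along
boundaries, the windows deliver outliers spectrally adjacent to the target:
exactly the points a too-loose sphere accepts first. A size-matched
`build_random_validation_set` (same target/outlier counts, uniform over the
scene) is provided as the conventional comparator.

## Simulated annealing over (C, s)

Fixed by the method definition: error = #wrong/(#correct+#wrong) with
correct outlier rejections excluded; Metropolis acceptance
`exp(−ΔE/(k_B·T))`; geometric cooling `T ← ρT` with ρ = 0.9; search box
[0.01, 1] × [0.01, 20].

Choices this package had to make, with the reasoning:

- **Temperature scale.** k_B = 1 and T₀ calibrated from 20 warm-up probes
  so a typical worsening move is initially accepted with probability ≈ 0.8;
  the run cools until `T < 10⁻³·T₀` (≈ 66 levels), with 10 Metropolis steps
  per level, an incumbent-stall cutoff of 200 evaluations, and an optional
  hard evaluation cap.
- **Log-scale geometry.** Both C and s are proposed on a log scale
  (Gaussian step of 0.1 × log-range × T/T₀, reflected at the box walls),
  and warm-up/initial states are drawn log-uniformly. C spans two decades
  and s three; the informative low-C region occupies a few percent of C's
  linear range, and experiments with linear-C proposals showed the walk
  reliably failing to visit it within the cooling budget.
- **Warm start and re-annealing.** The anneal starts from the best warm-up
  probe, and the current state is reset to the incumbent best at each
  temperature drop. Without the reset, the cold (exploitative) phase
  refines whatever random state the hot phase happened to end in; with it,
  the final descent always localizes the best basin found. The incumbent
  best over *all* evaluations is returned regardless.
- **Stall cutoff 200, not shorter.** A short stall window (e.g. 50
  evaluations) triggers a handful of temperature levels into the schedule,
  while acceptance is still near-random — it measures patience, not
  convergence. 200 evaluations ≈ 20 levels without improvement is long
  enough that the geometric floor usually terminates the run instead.

Determinism: one `numpy` Generator seeded from `SAConfig.seed` drives
probes, proposals and acceptance; identical inputs and seed reproduce the
trace bit-for-bit. The pipeline derives per-stage seeds (training
subsample, random validation, annealer) from its single seed via
`SeedSequence`.

## Accuracy assessment and upscaling

The confusion matrix is binary (target/outlier), rows = reference,
columns = prediction; PA = tp/(tp+fn), UA = tp/(tp+fp), OA = (tp+tn)/N,
kappa = (OA−p_e)/(1−p_e) with p_e the usual marginal-product chance
agreement. Undefined ratios (empty denominators) are reported as NaN and
flagged, never silently zeroed. Unknown/nodata pixels are excluded.

Coarser resolutions are simulated by block-mean spectral aggregation
(factor×factor blocks; trailing partial blocks dropped rather than padded,
so no spectra are fabricated). The matching reference is the fine-label
target-fraction map thresholded by the strict majority rule: fraction
> 0.5 is target, exactly 0.5 is outlier.

## The synthetic scene generator

`generate_scene` emulates a fragmented agricultural landscape:

- **Geometry**: a rectangular tessellation with randomized block sizes
  (uniform in [0.6, 1.4] × mean size); each cell is assigned a class by a
  weighted draw. Edges carry a continuous sub-pixel offset in (−0.5, 0.5),
  so boundary pixels receive area-overlap fractions distributed over (0, 1)
  — mixed pixels are *dominated* by one of the two classes, as real
  boundary pixels are — rather than sitting at exactly 50/50. Explicit
  integer edge positions (used in tests) put the edge through a pixel
  centre and produce the exact 0.5/0.5 seam.
- **Mixing**: `mixing_width` is the total width (in pixels) of the linear
  transition band centred on each edge; width 1 reproduces exact
  area-weighted mixing with a single mixed column. Per-pixel spectra are
  `Σ_c f_c · x_c` with `x_c ~ N(μ_c, Σ_c)` drawn per class per pixel and
  `f_c` the recorded fractions, which sum to 1 by construction.
- **Truth**: hard labels are the argmax of the fractions (ties to the
  lowest class code), plus the full fraction maps for majority-rule
  references.

`canonical_scene_spec` fixes the canonical study conditions used by the
acceptance suite: 4 bands, 200×200 pixels, mean parcel edge 20 px (≈ 48 m
fields at a 2.4 m ground sample distance — fragmented smallholder
agriculture), mixing width 1, isotropic per-class noise with SD 0.015 in
reflectance units, and four covers with weights wheat 0.40 / bare land
0.25 / trees 0.20 / water 0.15. The class means place bare land nearest to
wheat in band space (Euclidean 0.053, about 1.8× the pooled noise SD
√tr(Σ) = 0.03), trees intermediate (0.142) and water far (0.42) — the
adjacency ordering that makes the one-class problem interesting: bare land
genuinely overlaps the wheat cloud's skirt, water is trivially rejectable.

What the generator deliberately does **not** model: sensor point-spread
functions, atmospheric and illumination effects, within-field trends and
spatially correlated texture, curved or irregular parcel shapes, and class
covariances richer than the isotropic default (full covariances are
supported but not used by the canonical spec). Passing tests on these
scenes therefore demonstrate the *method's mechanics* — sampling,
optimization, classification and assessment behaving as designed — not
performance on real imagery, where target heterogeneity is the dominant
difficulty.

A consequence worth knowing: excluding the spectrally distant class from
the validation set changes nothing *exactly*, because the error criterion
ignores correctly rejected outliers and every candidate sphere rejects the
distant class. The robustness to untrained distant classes is thus
structural, not statistical.

## Numerical details

- SMO: KKT-gap tolerance 1e−8, iteration cap 10⁵, duplicate-point (η = 0)
  steps take the full feasible transfer.
- Decision rule boundary inclusive (`d² ≤ R²`); raster classification is
  vectorized in 65 536-pixel chunks; nodata maps to the unknown code.
- MNF ridge regularization triggers at condition number > 1e12.
- Convex hull via scipy's Qhull, with an extreme-points-along-MNF1 fallback
  for collinear clouds.
- Aggregation and fraction maps drop trailing partial blocks; fraction 0.5
  → outlier (strict).
- Raster I/O: multiband TIFF (via tifffile, metadata in the image
  description tag) and an ENVI-style BSQ binary with text sidecar header;
  both round-trip float64 losslessly. Coordinates are 0-based (row, col),
  row 0 at top, everywhere.

## Problem sizes

The canonical experiments use 200×200-pixel scenes, 120 training pixels,
3×3 windows (≈ 750 target / 180 outlier validation pixels) and annealing
runs of a few hundred SVDD fits; the acceptance script averages five scenes
per condition. These sizes keep a full multi-condition study in the
minutes range on one core while leaving every effect it measures far from
small-sample noise (each map decision is over 40 000 pixels).

## Known limitations

- The annealer optimizes the validation error, which is a plateau-prone,
  quantized objective; different seeds can land on different (C, s) with
  similar validation error but visibly different maps (single-scene OA on
  the canonical conditions varies by a few points across seeds).
- The validation windows see only the immediate neighbourhood of the
  training boundary; heterogeneous target spectra far from any boundary are
  under-represented, which biases the sphere small (high UA, lower PA at
  fine resolution — visible in the examples).
- The C = "ratio of target to outlier objects" reading sometimes attached
  to SVDD conflicts with the standard slack-penalty dual bound; this
  package implements the standard dual (`0 ≤ α ≤ C`, `Σα = 1`).
- Binary (target/outlier) assessment only; no area-adjusted accuracy
  estimators; no negative-example SVDD; RBF kernel only; no geometric or
  atmospheric preprocessing.
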