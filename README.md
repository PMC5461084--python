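# svddmap

One-class land-cover mapping with support vector data description (SVDD),
window-based validation sets, and simulated-annealing hyperparameter search.

## The problem

Mapping a *single* land-cover class (say, winter wheat) from a multispectral
image is awkward for multi-class classifiers: they need exhaustive training
data for every other cover in the scene, and an *untrained* class silently
leaks into the target map. One-class classifiers need target examples only —
SVDD fits the smallest hypersphere that encloses the target spectra in
RBF-kernel feature space and rejects everything outside it. The catch is
choosing its two hyperparameters:

- **C** — the tradeoff coefficient, an upper bound on each dual weight.
  Lowering C pushes training points out of the sphere and tightens the
  description.
- **s** — the RBF kernel width in `K(x, y) = exp(−‖x−y‖² / s²)`, which sets
  how compact the boundary is.

Cross-validation cannot tune them: with target-only training data, *any*
sphere big enough to swallow the training set looks perfect. This package
implements the window-based remedy: the training set is built from *edge*
pixels (mixed pixels along target parcel boundaries plus "corner" pixels at
the convex-hull vertices of the target cloud in the MNF1–MNF2 plane), and a
validation set is sampled from the w×w windows around each training pixel.
Those windows straddle parcel boundaries, so they contain *informative
outliers* — spectra adjacent to the target class — which punish a loose
sphere. Simulated annealing then minimizes the validation error

```
Error = #wrong / (#correct + #wrong)
```

(`#correct` = validation targets accepted; `#wrong` = targets rejected +
outliers accepted; correctly rejected outliers are not counted), with
Metropolis acceptance `exp(−ΔE/(k_B·T))` and geometric cooling `T ← ρT`
(ρ = 0.9) over the box (C, s) ∈ [0.01, 1] × [0.01, 20].

For a spectrum z, the fitted model accepts z as target iff

```
d²(z) = 1 − 2 Σᵢ αᵢ K(xᵢ, z) + Σᵢⱼ αᵢαⱼ K(xᵢ, xⱼ)  ≤  R²
```

where α solves `min αᵀKα  s.t.  Σα = 1, 0 ≤ αᵢ ≤ C` (solved in-package by
sequential minimal optimization) and R² is read off the unbounded support
vectors. Accuracy is assessed with the standard confusion-matrix metrics
(producer's/user's/overall accuracy, Cohen's kappa), and multi-resolution
experiments are supported through block-mean spectral aggregation and
majority-rule (fraction > 0.5) reference maps.

Because no public scene ships with the package, a synthetic-scene module
generates fragmented-parcel multispectral landscapes with per-pixel ground
truth: Gaussian class spectra, sub-pixel parcel edges, and linear
area-weighted mixing at boundaries — enough structure to exercise every
stage of the method.

## Worked example

```python
import svddmap as sm

spec = sm.canonical_scene_spec(seed=0)          # 4-band, 4-class crop scene
raster, truth = sm.generate_scene(spec)
result = sm.run_oneclass_mapping(
    raster, truth.labels, target_code=spec.target_index, window=3, seed=0
)
```

Running `python examples/simulate_and_map.py` (which does exactly this)
prints:

```
scene: 4 bands, 200x200 px, classes: ['wheat', 'bare_land', 'trees', 'water']
training pixels : 120 (60 mixed boundary + 60 MNF corner)
validation set  : 745 target / 186 outlier pixels (3x3 windows)
annealed optimum: C = 0.041, s = 18.11 (validation error 0.077, 489 SVDD fits)
map accuracy    : OA = 88.2%  PA = 97.8%  UA = 75.1%  kappa = 0.756
```

The 120 training pixels are all wheat; the annealer settles on a small C
(tight description) and scores 0.077 on the window validation set; the
resulting map recovers 97.8% of true wheat (PA) while 75.1% of mapped wheat
is real (UA). The other scripts in `examples/` demonstrate the C/s geometry,
the window-vs-random validation comparison, and multi-resolution assessment.

A thin CLI mirrors the library: `svddmap simulate | select-train |
select-val | optimize | classify | assess | aggregate | run` (see
`svddmap --help`).

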