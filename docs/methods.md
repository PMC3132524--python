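# Methods

This note records the model, its tunable parameters, the numerical choices
made where the design was genuinely open, what the synthetic phantoms do
and do not emulate, and the known limitations.

## Model and assumptions

The segmenter is a per-pixel supervised classifier. The core assumption is
that a pixel's class is predictable from the raw intensities in a small
window around it, provided the window is observed at several resolutions:
fine scales carry local texture, coarse scales carry regional context.
No spatial regularization (MRF, graph cut, morphology) is applied to the
output — the label map is exactly the pixelwise argmax of the voted
posterior, so spatial coherence comes only from the overlap of neighboring
windows and from the smoothed coarse scales.

The pipeline stages and their contracts:

1. **Normalization** (`pixelseg.io.normalize_intensity`). Per channel,
   intensities are mapped by `(x − q_lo)/(q_hi − q_lo)` clamped to [0, 1],
   where `q_lo, q_hi` are the `clip_fraction` and `1 − clip_fraction`
   quantiles (linear interpolation of sorted values). Default
   `clip_fraction = 0.01`. This makes features invariant to positive
   affine intensity changes (gain/offset) but not to nonlinear or
   spatially varying distortions; no bias-field or stain correction is
   attempted. Channels are treated independently because downstream the
   channels are simply extra feature entries. A constant channel maps to
   zeros with a warning so batch jobs survive degenerate inputs.

2. **Multiscale windows** (`pixelseg.neighborhoods`). Scale s smooths with
   an isotropic Gaussian, σ₀ = 0 and σₛ = 2^(s−1) for s ≥ 1, truncated at
   4σ, and samples the window grid with stride 2ˢ. The σ schedule is an
   anti-aliasing choice proportional to the stride; it is not derived from
   data. Windows are flattened row-major with the channel index fastest;
   any fixed order works as long as train and test agree. Out-of-bounds
   samples replicate the nearest edge pixel, which keeps every pixel
   classifiable at every scale at the price of slightly flattened
   statistics near borders.

3. **Pixel typing and augmentation.** A pixel is boundary-type when the
   `type_window` (default: the patch side N) around it contains two or
   more distinct labels, interior-type otherwise. The two-or-more reading
   was chosen deliberately: a window straddling exactly two tissues is the
   canonical boundary case. Only boundary windows are augmented — rotations
   about the Z axis by ±45° plus left-right and up-down flips of every
   rotated version (3 × 3 = 9 windows with the defaults). Rotation is
   applied to the window grid, not the whole image: inside the window the
   two are equivalent under bilinear interpolation, and the window-level
   operator is a precomputable linear map (built by rotating one-hot basis
   windows with `scipy.ndimage.rotate`, order 1, edge-replicated), which
   makes augmentation a matrix multiply over the patch batch. For 3D
   windows the rotation acts on each X-Y slice; flips stay in the X-Y
   plane.

4. **Subset selection** (`pixelseg.sampling`). Budget Q per scale
   (default 5000). Spatial regions: K-means on pixel coordinates with
   K = R (default 4). Cell quotas are proportional to cell size with
   largest-remainder rounding, capped at availability; quotas of cells
   absent from a pool redistribute among same-class siblings. Inside a
   cell, K-means with K = quota runs in feature space and the member
   nearest each centroid is kept — representatives are always observed
   windows, never centroid blends (centroids of rotated windows could be
   unrealistic). K-means uses k-means++ with 10 restarts for K ≤ 32 and a
   single greedy k-means++ initialization for larger K, 300-iteration cap,
   tolerance 1e-4; the restart cutoff trades a marginally better inertia
   for a large constant-factor speedup at quota sizes in the hundreds.

5. **Per-scale SVM** (`pixelseg.classifier`). RBF kernel; hyperparameters
   (φ, γ) by two-stage stratified 10-fold CV: broad grid
   φ ∈ 2^{−5..15}, γ ∈ 2^{−15..3} with ×4 steps; a bound is pushed out ×5
   and the broad stage repeats while *every* CV optimum sits on that
   bound; then a fine ×√2 grid over ±1 broad step. Ties resolve to the
   median of the tied plateau rather than an extreme: in the small-φ limit
   the decision boundary can still separate while the Platt-coupled
   posteriors collapse toward uniform, and the ensemble consumes
   posteriors, so tie-breaking toward small φ would silently destroy
   confidence voting on separable data. For the same reason the predicted
   label is defined as the argmax of the coupled posterior (one mechanism
   for labels and confidences). Hyperparameter selection runs on a
   class-stratified subsample (default 1024) with a 2×10⁴ iteration cap —
   it only ranks parameter pairs; the final model refits on the full
   selected set with a 2×10⁵ cap and LibSVM-style internal Platt
   calibration.

6. **Voting** (`pixelseg.ensemble`). Weighted confidence voting maximizes
   training-pixel accuracy over an exhaustive grid on the weight simplex
   (step 0.1; 1001 candidates for 5 scales) — valid because the argmax is
   invariant to positive rescaling of the weights, and appropriate because
   accuracy is piecewise constant in the weights, so gradient methods have
   nothing to follow. Weights are fit on the training images' own pixels
   (capped at 20 000 sampled pixels); fitting them on held-out folds
   instead is possible by passing a different probability stack to
   `optimize_weights`. Ties prefer fewer nonzero weights, then the vector
   with the largest leading weights, so degenerate ties return one-hot on
   scale 0. All label ties anywhere break toward the smallest class index.

## Evaluation metrics

* Dice of two empty sets is defined as 1.0 (vacuous perfect agreement).
* Rand index: pair-counting on the label contingency table, equal to the
  fraction of unordered pixel pairs whose co-membership agrees. The
  Jaccard companion is `(n11 + n00)/(n00 + n10 + n01)` on the same pair
  counts — agreements normalized by all pairs except those co-clustered in
  both partitions — which is why it has no upper bound.
* Hausdorff and NSD measure distances from disagreeing pixels to the
  *reference border* (truth mask minus its erosion) via a Euclidean
  distance transform. NSD normalizes the sum of those distances over the
  symmetric difference by the same sum over the union of both masks: this
  normalizer is the one consistent with both anchor points (0 for
  identical masks, 1 for disjoint masks).
* Object error counting matches every object to the counterpart sharing
  the most pixels (background allowed; ties to the lowest label):
  split/merged count excess many-to-one matches, added/missing count
  objects whose plurality partner is background.

## Synthetic phantoms

The generators produce the three structural regimes the pipeline targets,
with exact ground truth and full determinism under a seed:

* `texture2d`: Voronoi partition of the plane (irregular, curved
  boundaries that exercise the boundary-pixel logic; a `halves` layout
  with one straight interface exists for exact boundary-count tests), each
  class filled with Gaussian-filtered noise at a class-specific
  correlation length around a class-specific mean intensity or color, plus
  additive noise. Defaults: 128×128, 3 classes, class means evenly spaced
  in [0.2, 0.8], texture amplitude 0.08 with correlation lengths 1–3 px,
  additive noise σ = 0.03 — classes that are clearly separable by a 3×3
  neighborhood yet overlap enough that no single threshold solves the
  task.
* `volume3d`: nested ellipsoid shells with distinct means, optional smooth
  multiplicative drift (low-frequency field) to stress robust
  normalization.
* `nuclei2d`: non-overlapping random ellipses (bright on dark, blur σ = 1,
  additive noise), per-object ids in the label map.

What the phantoms do **not** emulate: real histology's stain variability
and structured textures, MRI partial-volume effects and scanner noise
statistics, and touching/overlapping nuclei. Passing the phantom suite
therefore demonstrates that the machinery is correct and that the method
solves problems with this covariance structure at these noise levels — it
does not certify accuracy figures on any real modality.

Default problem sizes in the test suite and acceptance script (two
128×128 training phantoms at Q = 5000 and 5 scales for the texture run;
two 96×96 phantoms at Q = 2000 for the nuclei run) were chosen so a full
train+segment cycle completes in minutes on a single CPU while leaving the
classifiers enough data to reach their accuracy plateau.

## Numerical choices and degenerate inputs

* Quantiles by linear interpolation of sorted values (`np.quantile`
  default), matching the documented normalization contract exactly.
* A constant channel normalizes to zeros (warning, not an error).
* `allocate_quotas` hands out largest-remainder units in deterministic
  order (remainder, then cell index); `select_representatives` breaks
  nearest-to-centroid ties by lowest record index; empty K-means clusters
  are topped up deterministically from unused records.
* All stage seeds derive from the single run seed via `SeedSequence`
  tagged per stage, so stages can be re-run in isolation with identical
  results.
* Label rasters are stored as unsigned 16-bit integers; class 0 is an
  ordinary class with no background semantics at the I/O layer.

## Known limitations

* Training cost is dominated by per-scale grid search; it is bounded by
  the grid-search subsample, not by Q, so very large Q mainly slows the
  final fits and segmentation.
* The weight search is exhaustive on a simplex grid; its resolution
  (default 0.1) bounds how finely the ensemble can trade scales off.
* No post-processing: small spurious openings inside objects (visible in
  nuclei-style tasks) are left as-is by design; a morphological closing
  would remove them but is out of scope.
* Class imbalance is handled only through proportional quotas; rare
  classes receive proportionally few representatives.
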