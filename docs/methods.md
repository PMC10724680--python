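# Methods

## Problem and model

Pooling T1-weighted brain MRI across scanners introduces non-biological
variability (field strength, vendor, acquisition parameters).  `cycleharm`
implements whole-volume, unpaired harmonization of such data with a 3D
CycleGAN: two U-net generators translate volumes between a source site and a
reference site, two patchGAN discriminators score local realism, and an L1
cycle-consistency penalty ties the round trip back to the input.  Reference-
site images are never modified; only source-site images are mapped into the
reference domain.

Losses are least-squares adversarial terms plus `λ(t) · L1` cycle terms, with
`λ` decaying linearly from 200 to 100 over the run.  Generators train with
batch size 1; each discriminator trains per step on a batch of 4 real images,
2 newly generated images and 2 images drawn from a 50-image history buffer of
former generations (Shrivastava-style pool: below capacity the offer is
stored and returned; at capacity the offer is returned unchanged with
probability 1/2, otherwise swapped against a uniformly chosen stored image).

Architectural choices that matter:

* **Strided convolutions only.**  The generator encoder is a stack of
  stride-2 4×4×4 convolutions (leaky slope 0.2); the decoder is stride-2
  transposed convolutions with concatenated skips.  No stride-1 refinement
  blocks, no resize convolutions.
* **Non-negative open-ended output.**  The final activation clamps negatives
  to zero and is the identity above zero, so the generator can produce
  intensities above any fixed ceiling (a tanh head cannot).
* **Masked generation.**  The input's brain mask is re-applied after every
  generation; background voxels are exactly zero and cannot leak gradients.
* **MAD instance normalization.**  Normalization layers divide by the mean
  absolute deviation rather than the standard deviation:
  `y = (x − mean) / (mad + eps) · gain + offset`, `mad = mean|x − mean|`,
  per channel per instance over space.  The MAD is *not* rescaled by
  √(π/2); a `rescale` switch restores SD-like scaling for comparison.
  `eps = 1e-5`.
* **PatchGAN receptive field 38.**  Three (4, stride 2) stages and one
  (3, stride 1) output stage give RF = 4 + 3·2 + 3·4 + 2·8 = 38 voxels per
  axis, verified empirically by the gradient footprint of a single output
  unit.  The footprint probe disables instance normalization: per-instance
  statistics couple all spatial positions and would report the whole grid
  rather than the convolutional footprint.

The networks and their gradients are implemented on a compact numpy
reverse-mode autodiff engine (`cycleharm._ad`): im2col convolutions around
single BLAS matmuls, with transposed convolution, input-gradient and
weight-gradient implemented as the three adjoint faces of one primitive.
All op gradients are finite-difference-tested.  An optional reduced-precision
policy (`mixed_precision`) stores activations as float16 while computing in
float32; a one-step equivalence test bounds its deviation from full
precision.

## Intensity scale

Volumes enter training median-normalized (brain median = 500).  Internally
the trainer divides intensities by the median target so the networks operate
on a brain-median-1 scale; with O(1) voxel values the λ = 100–200 cycle
weight is commensurate with the O(1) least-squares adversarial loss.
Generator outputs are rescaled back to intensity units.

## Preprocessing

Skull-stripping, bias-field correction and affine registration are external;
the package consumes masked, registered volumes.  In scope: median-500
normalization (pure rescale; idempotent; background untouched), pad/crop to
a cube (default 192, never discarding a brain voxel; bounding-box center
maps to grid center with ties toward the lower index), and brain-intensity
histograms (100 bins over [0, 900]).  Intensities above the ceiling are
ignored, not clipped, and the ignored count is reported so that counts always
reconcile with the brain-voxel total; the median uses the midpoint
convention for even counts.

## Synthetic phantoms

The simulator emulates the features of multi-site structural MRI that the
evaluation suite measures, at a fraction of the cost:

* **Anatomy** — nested deformed ellipsoids (WM core, GM shell, CSF rim) with
  smooth per-subject radial perturbations; the radial coordinate is
  homogeneous of degree 1, so shell volume fractions are exact differences of
  cubed radii.  Partial volumes come from Gaussian-smoothing hard labels
  (σ = 0.7 voxels) and renormalizing inside the mask, giving the residual
  partial-volume metrics a nonzero, controlled ground truth.
* **Aging** — the brain-relative GM fraction follows
  `0.45 − 0.0015·(age − 20)` (GM converted to CSF; WM and intensities
  age-independent), isolating the biological covariate harmonization must
  protect.  The decline (~0.09 over six adult decades, relative to an
  age-20 baseline of 0.45) is in the range reported for adult cortical
  gray-matter loss; only its linear shape is exploited by tests.
* **Intensities** — tissue means (CSF 150, GM 300, WM 450 a.u.), ±4 %
  per-subject jitter, within-tissue texture SD 8.
* **Site effects** — applied in a fixed order: per-tissue contrast
  multipliers (partial-volume-weighted) → gamma on brain intensities
  rescaled to [0, 1] by the brain max → unit-mean smooth multiplicative bias
  field (seeded Gaussian random field, peak fractional deviation =
  amplitude) → global scale → additive Gaussian noise inside the mask.
  Background stays exactly zero.  With zero noise the transform is a
  monotone map composed with strictly positive fields and is inverted by
  `invert_site_effect` to ~1e-16 relative error.
* **Presets** — two illustrative site styles differing in gamma
  (0.85 vs 1.20) and GM/CSF contrast, i.e. differences that *survive*
  median normalization, plus scale/bias/noise.  They are not calibrated to
  any real scanner pair.
* **Traveling subjects** — paired cohorts share anatomy and age and differ
  only in site effect and noise realization.

Everything is a pure function of parameters and one integer seed.

What phantoms do **not** model: cortical folding, lesions, acquisition
physics, scanner-specific texture.  Consequently passing tests demonstrate
that the pipeline removes global-intensity-statistics site effects while
preserving a volumetric aging covariate — not that it handles the texture-
level site effects of real multi-vendor data.

## Training at desk scale

The test suite and worked examples run two-site experiments at 48³ voxels
with 20 subjects per site and reduced channel counts (generator depth 2,
base 8–16; discriminator channels 8/16/32); the reference two-site run uses
800 identity-pretraining steps, 300 discriminator warm-up steps and 700
joint steps (~10 min on one CPU).  Three adaptations make the adversarial
game converge at this scale:

1. **Norm-free discriminators.**  Instance normalization removes exactly the
   per-instance global intensity statistics that constitute the site signal
   of smooth phantoms; a supervised probe confirmed an instance-normalized
   site classifier cannot separate the presets while a norm-free one can.
   Real MRI carries normalization-surviving texture; phantoms do not.  The
   `normalization` flag of the discriminator spec is off in the desk-scale
   runs (architecture otherwise unchanged).
2. **Discriminator warm-up** (`disc_warmup_steps`): standard discriminator
   updates against the identity-initialized generators' fakes before the
   first generator update, so the generator receives a meaningful
   adversarial gradient from step 0 of a short run.
3. **Two-speed Adam** (`disc_learning_rate`): discriminators at 1e-3,
   generators at 2e-4–5e-4 (betas 0.5/0.999 throughout).  At full scale the
   conventional single rate (2e-4) remains the default.

Identity pretraining (L1 replication of pooled-site inputs, Adam lr 1e-3)
initializes both generators; at 48³ with 20 subjects per site, 800–1200
pretraining steps bring held-out reconstruction error below 5 % of the brain
median.  A non-finite loss aborts training with a diagnostic state dump.

Age-balanced sampling: ages are binned (default 10-year bins); both sites
share per-bin probability `q(b) ∝ min(n_A(b), n_B(b))` (zero if a bin is
empty in either site), uniform within bins.  Both streams then have the same
expected age distribution, and the limiting site per bin is used maximally
rather than undersampled.

## Evaluation suite

* Tissue volume fractions normalized by intracranial volume; partial-volume-
  weighted moments by default, hard ≥ 0.5 masks available for parity with
  hard segmentations.
* IQMs: cjv = (σ_WM + σ_GM)/|μ_WM − μ_GM|; efc = entropy of the intensity
  distribution normalized by the maximum-entropy value (1 for a constant
  image, 0 for a single bright voxel); per-tissue SNR = μ/(σ·√(n/(n−1)));
  wm2max = WM median / brain P95 (percentiles by linear interpolation —
  documented because wm2max depends on it); rpve in percent with
  f(p) = p for p ≤ 0.5 and 1 − p above; FWHM by the classic first-difference
  estimator, geometric mean over axes, undefined axes excluded with a
  warning.
* First-order radiomics: the 18 standard features (energy … uniformity; the
  plain SD is excluded as redundant with variance) per region over GM and WM
  hard masks → a fixed-order 36-vector.  Discretization uses fixed bin
  width 25, anchored at `floor(min/width)·width`, with the maximum keeping
  its own bin.  Kurtosis is not excess-corrected.
* PCA: standard-scaled columns, top-2 axes, variance-explained reported;
  constant columns dropped with a warning.
* SSIM (3D): uniform 7³ window, C1 = (0.01·R)², C2 = (0.03·R)², fixed range
  R = 1000, after cropping both volumes to their joint nonzero bounding box
  (background-slice removal).  Matches the scikit-image reference
  implementation to 1e-6 on dense volumes.
* Histogram statistics: Euclidean distance between averaged histograms; the
  multisite heterogeneity index is the sum over bins of the across-site
  sample SD (n−1) of per-site mean counts.
* Brain-age errors: MAE, MPAD (mean predicted − real), TMD (training-mean −
  test-mean age).  The CNN age predictor itself is out of scope.
* Fallback segmentation: per-volume 1D k-means (3 classes, quantile
  initialization, classes ordered CSF < GM < WM), softened like the
  simulator's partial volumes.  A Gaussian-mixture soft alternative was
  evaluated and rejected: its posteriors depend on fitted variances and are
  far less stable under intensity remapping.
* The GM-fraction–age correlation is evaluated on the pooled dataset
  (harmonized source + untouched reference) under one *common* segmentation
  model: class boundaries fitted on pooled reference-site voxels
  (`fit_class_boundaries`) and applied fixed to every volume.  This mirrors
  a multi-site pipeline in which all images are segmented identically, and
  it is deliberately site-sensitive: per-volume adaptive clustering is
  intensity-scale invariant — effectively a quantile harmonizer — and would
  hide exactly the site effect whose removal is being evaluated.

## Numerical and degenerate-input policy

Metrics that are mathematically undefined for an input (zero variance, equal
tissue means, empty region) raise typed errors; the batch `iqm_set` reports
them as NaN instead of failing the whole volume.  Histograms with mismatched
edges, empty masks and undersized grids are rejected, never coerced.
Float32 is used inside the networks, float64 everywhere else.

## Known limitations

* Phantom realism limits (above); all end-to-end evidence is at 48³.
* The numpy engine is single-threaded BLAS-bound; full-scale 192³ training
  is out of reach — the implementation targets method-level fidelity, not
  throughput.
* The published age-range probability-assignment algorithm is not public;
  the min-rule used here satisfies the same stated objectives but may differ
  from the original.
* Histogram out-of-range handling (ignore vs clip) is configurable because
  the reference behavior is unstated; defaults ignore and count.
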