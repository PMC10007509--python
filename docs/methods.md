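# Methods

## Problem setting

Reconstruction-based anomaly detection trains a generative model on
normal images only. Structures absent from the training distribution —
here, breast masses and tumors, which appear as hypoechoic (dark) regions
in ultrasound — reconstruct poorly, so they surface as large values in
the per-pixel error image ("anomaly map") `|x − x̂|`. Thresholding that
map yields a pixel-level lesion segmentation without any lesion labels at
training time.

## Models

All three variants share one backbone so that differences in detection
performance are attributable to the objective, not capacity: stride-2
3×3 convolutions (default widths 16→32→64→64) with batch normalization
and LeakyReLU (slope 0.2), a flattened dense bottleneck (default
`latent_dim = 128`), a mirrored decoder of 4×4 stride-2 transposed
convolutions, and a sigmoid output that confines reconstructions to
(0, 1). A `spatial_bottleneck` mode replaces the flatten/dense head with
1×1-style conv heads, keeping the code's spatial layout, to support
experiments on whether dimension reduction in the encoder matters.

- **AE** minimizes the L1 distance; the per-pixel error it optimizes is
  exactly the statistic used for detection.
- **VAE** adds a closed-form Gaussian KL term
  `−½ Σⱼ (1 + log σⱼ² − μⱼ² − σⱼ²)` against a standard-normal prior; the
  latent sample is reparameterized as `z = μ + εσ`. At inference the
  posterior mean μ is decoded (no sampling) so anomaly maps are
  deterministic; sampling is available by flag. The reconstruction term
  is L1 by default, with Bernoulli cross-entropy as a config option (the
  literature states both forms; the prose description of the loss is
  taken as authoritative).
- **SWAE** replaces the KL with the empirical sliced-Wasserstein distance
  between the batch of latent codes and an equal-size standard-normal
  draw: project both sets onto L random unit directions (default 50),
  sort the projections, and average the squared differences of order
  statistics. Sorting solves 1-D optimal transport exactly for equal-size
  sets, which is why the estimator is restricted to equal batch sizes.
  The reconstruction term is the pixel MSE.

### Loss weights and scaling

The prior-matching weights are not fixed by the source protocol, so the
defaults are conventional and exposed in config: VAE β = 1.0, SWAE
λ = 10.0, 50 projections. For optimization the summed L1/KLD objectives
are divided by the pixel count; this leaves the balance of the two terms
(and hence the optimum) unchanged while making logged losses per-pixel
means comparable across image sizes. The SWAE objective already uses a
mean (MSE) reconstruction term, and λ weighs the SWD against it directly.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), batch 16, maximum learning rate 2·10⁻⁴
annealed along one half-cosine per run — `lr(t) = lr_min + (lr_max −
lr_min)(1 + cos(πt/T))/2`, evaluated per epoch, no warm restarts (the
simplest reading of "cosine annealing"; whether the original schedule was
per-step or restarted is unstated). The default protocol is 150 epochs;
desk-scale runs use far fewer. Gamma-corrected copies (γ = 0.5, 1.5) of
the training split are appended as augmentation by default; validation
and test data are never augmented. The last incomplete batch is kept so
small datasets lose no data (the SWAE prior draw matches the actual batch
size). Training is seeded end-to-end — initialization, shuffling, VAE
noise, SWAE prior and projection draws — so identical configurations
reproduce identical histories; a non-finite loss raises a typed
divergence error naming the epoch rather than propagating NaN.

The networks run on a small numpy layer library with manual
backpropagation (im2col/col2im convolutions, standard batch-norm
backward). Every layer and all three end-to-end objectives are checked
against numerical differentiation in the test suite. float64 is used
throughout: the models are small, and bit-reproducibility is worth more
here than speed.

## Threshold selection

Anomaly maps are binarized with a strict `>` comparison ("larger than the
threshold"). Besides the fixed grid {0.1, 0.2, 0.3}, a threshold can be
derived from the normal validation split: compute the average of the
validation anomaly maps, rectify each map's residual against it with
ReLU, and take the maximum over all maps and pixels. The "average" is
read as the per-pixel mean map (the baseline a residual is measured
against); the alternative scalar-grand-mean reading is available via
`baseline='scalar'`. Because ReLU discards negative residuals, this rule
yields large thresholds (≈0.5 on the synthetic benchmark) that flag
almost nothing — reproducing the behavior that motivated the fixed grid.
No morphological post-processing is applied to predicted masks.

## Evaluation

- RMSE between input and reconstruction, averaged over a split; the
  headline is the macro average (mean of per-image RMSE), with the
  pooled-pixel micro average reported alongside, since the aggregation
  used for the original tables is unstated.
- Dice = 2TP/(2TP+FN+FP), TPR = TP/(TP+FN), FPR = FP/(FP+TN) over pixels.
  Degenerate denominators (never met by clinical data where every test
  image has a lesion, but reachable synthetically): both masks empty →
  dice 1, fpr 0, tpr undefined (NaN, excluded from means); truth empty
  but prediction nonempty → dice 0, tpr undefined.
- Threshold sweeps compute each anomaly map once and re-threshold it, so
  TPR/FPR monotonicity in the threshold is exact on the fixed map set
  (Dice is not monotone and is not asserted to be).
- Lesion-size stratification bins lesion pixel areas by quantiles
  (default 5 bins) so bins stay populated at any dataset scale; bins are
  merged with a warning when there are fewer distinct sizes than bins.

## Synthetic phantom

The generator emulates the *statistical shape* of the task, not
ultrasound physics:

- **Background**: Gaussian-filtered white noise (scale `smoothness`,
  default 8 px) min–max rescaled to [0.2, 0.8] — smooth tissue-like
  texture with headroom for contrast in both directions.
- **Speckle**: multiplicative unit-mean Rayleigh factors, linearly mixed
  with 1 by `scale` (default 0.3) and clipped to [0, 1]; a standard
  first-order speckle surrogate. The pre-clipping expectation equals the
  input image.
- **Lesions**: exactly one ellipse per abnormal image, pixel area uniform
  in [50, 400] px, aspect ratio 0.5–1, random orientation; interior
  pixels darkened multiplicatively by `1 − drop` with drop uniform in
  [0.3, 0.7] (hypoechoic contrast that preserves [0, 1]); boundary
  optionally Gaussian-softened (default 1 px). The ground-truth mask is
  the hard ellipse interior. Lesions are inserted before speckle so noise
  multiplies lesion and background alike.
- **Splits**: default 853 train / 94 validation normals and 200 abnormal
  test images; desk-scale default image size 64×64×1, configurable up to
  224×224×3.

What a green test on phantoms establishes: the estimators, thresholds,
metrics, training loop, and the *directional* model ordering (SWAE
detecting lesions better than AE at matched thresholds) behave as
specified. What it does not establish: performance on real
ultrasonography — the phantom has no attenuation, shadowing, anatomy, or
operator variability, and its intensity statistics are a stand-in, since
the original images' statistics are uncharacterized.

## Numerical choices

- Strict `>` binarization means pixels exactly at the threshold are
  negative; applying a validation-derived threshold back to the
  validation maps therefore never flags the maximizing pixel.
- Averages over identical floating-point maps carry ~1e-16 roundoff; the
  "identical maps → threshold 0" contract is asserted at 1e-12.
- Gaussian filtering uses reflective padding to avoid dark-frame border
  artifacts that would inflate border anomaly scores.
- Per-stage seeds derive from one global seed as
  `crc32("<seed>:<stage>") & 0x7fffffff`, giving independent 31-bit
  stage streams without bookkeeping.
- 8-bit PNG is the interchange format; computation stays in float [0, 1]
  with quantization only at the I/O boundary (images round-trip within
  1/255, masks exactly).

## Known limitations

- Pure-numpy training is ~2 orders of magnitude slower than a GPU
  framework; the default conv widths (16→32→64→64) are chosen to train in
  CPU-minutes. Wider stacks are configurable but untested at scale.
- Image-level (whole-scan) anomaly scoring, GAN-based detectors, and
  benign-vs-malignant labeling are out of scope.
- The SWAE-over-AE ordering is asserted directionally over seeds, not as
  a quantitative replication of the original tables, which depend on
  private clinical data.
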