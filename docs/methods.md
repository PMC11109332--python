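# Methods

This note documents the models, procedures and numerical choices behind
`segpatch`, and what the synthetic benchmarks do and do not demonstrate.

## Problem setting

The unit of classification is the *connected component*: a maximal set of
voxels sharing one positive id in an integer label mask produced by an
upstream segmenter (0 is background; ids need not be contiguous). Given an
intensity image and its mask, each object is represented by a fixed-size
patch cut around its centroid, and a classifier maps patches to classes
1..9 (nine being the maximum number of classes supported by the annotation
scheme). Supervision is sparse: a handful of objects annotated by hand (or,
headlessly, imported from a ground-truth file), optionally grown by a
correction cycle in which a model's predictions are reviewed, corrected or
confirmed — never silently promoted — and fed back into training.

## Patch extraction

- **Centering.** The centroid is the floor of the mean voxel coordinate of
  the object. Per axis the crop spans `c − s//2 … c − s//2 + s − 1`;
  voxels outside the canvas are zero-filled. Floor rounding and constant
  zero padding keep extraction deterministic and dimension-agnostic, and
  padding invents no texture. Objects larger than the patch are truncated,
  not rescaled.
- **Mask channel.** By default the patch carries an extra binary channel
  holding the silhouette of the target object only (other objects zeroed).
  A crop can contain several objects; the extra channel tells the
  classifier which one is being classified. It can be disabled per config.
- **Normalization.** Three per-patch modes: `minmax` (affine rescale to
  [0, 1] by the patch's own extrema; a constant patch maps to zeros),
  `per_channel_minmax`, and `none`. Additionally `intensity_scale` divides
  intensity channels by a fixed global constant (e.g. 255 for 8-bit data)
  before extraction. The distinction matters scientifically: when absolute
  intensity is the class signal and the background is dark, per-patch
  min-max maps every object's brightest level to 1 and *cancels* the
  between-class intensity difference. Tasks where intensity discriminates
  should use `none` plus a global scale; tasks driven by texture or shape
  use `minmax`. The benchmark protocols below follow this rule.

## The classifier family

`d` blocks of `[conv k^dim (stride 1, same zero padding) → ReLU →
max-pool 2]` at constant width `w`, then global average pooling and an
affine map to `K` logits. Width and depth are the only architectural
degrees of freedom; the block structure itself (constant width, GAP head)
is this package's concretization of that two-parameter family, chosen as
the smallest standard design. The GAP head lets one spec serve any patch
size (45³ volumes and 137² slides alike). Max pooling truncates odd
trailing rows (floor semantics), so a patch must be at least `2^d` per
axis; violations fail with the minimum size in the message.

Trainable parameters follow the closed form
`C·w·k^dim + w + (d−1)(w²·k^dim + w) + w·K + K`, asserted against
introspection over random 2D/3D specs in the tests.

The network and its backpropagation are implemented directly on numpy
arrays (im2col + GEMM convolutions; gradients verified against numerical
differentiation), which keeps the package free of deep-learning framework
dependencies and bit-reproducible. Convolution weights use fan-in-scaled
uniform initialization seeded from the run seed; the affine head is
zero-initialized, so an untrained model outputs equal logits (first-epoch
cross-entropy starts at ln K exactly) and prediction ties are visible and
break deterministically toward the smallest class index.

## Training

Adam (default lr 1e-3, betas 0.9/0.999) on mean cross-entropy over
shuffled mini-batches (default batch 16), with the learning rate
multiplied by 0.5 every `⌈epochs/3⌉` epochs (step decay; both knobs
configurable). The default budget is 600 epochs. All randomness —
initialization, shuffling, augmentation draws, sampling — derives from the
config seed; two runs with identical config and seed produce bit-identical
checkpoints and predictions. A class declared but absent from the training
labels aborts with the class named; a non-finite loss aborts with the
epoch index. Optional inverse-frequency class weighting is available for
imbalanced label sets (off by default). Validation, when requested, is a
deterministic stratified split (per-class ceil rounding).

Augmentation is applied online, per sample per epoch, from an ordered
pipeline of named transforms with independent probabilities: built-ins
`hflip`, `vflip`, `rot90` (exact grid operations) and `rotate`
(free-angle, bilinear, constant fill); further transforms can be
registered by name. The mask channel is transformed identically to the
intensity channels. Orientation-sensitive tasks (the oriented-texture
benchmark) must not use rotation/flip augmentation — rotations destroy
the class-defining feature by construction — so the texture protocol runs
without augmentation.

## Prediction and outputs

Prediction is pure: no test-time augmentation, patches normalized exactly
as at training time (settings read from the checkpoint's JSON sidecar,
which stores the spec, patch settings and class names, making checkpoints
self-describing). Outputs per image are a table (object id, class,
confidence = max softmax probability), a class mask re-labeling each
object's voxels by predicted class (values 1..9, background 0 — a
viewer-independent encoding), and per-class counts. Batch mode pairs
images and masks across two folders by identical filename stem and aborts
with a listing if the pairing is not a bijection; per-image and batch
prediction are guaranteed identical.

## Evaluation metrics

From one-vs-rest confusion counts per class (`n_i` true members, TP, FP,
FN, TN), the report computes

    Precision = (1/N) Σ_i n_i·TP_i / (n_i·TP_i + FP_i)
    Recall    = (1/N) Σ_i n_i·TP_i / (n_i·TP_i + FN_i)
    F1        = 2·Precision·Recall / (Precision + Recall)
    Accuracy  = (1/N) Σ_i (TP_i + TN_i) / (TP_i + FP_i + TN_i + FN_i)

with N the number of classes. The `n_i` weighting inside the fractions is
implemented literally as displayed in the evaluation protocol this package
follows, even though it differs from the conventional support-weighted
mean; the conventional weighted precision/recall/F1 are computed alongside
(and cross-checked against scikit-learn) so both conventions are
available. Zero-denominator terms contribute 0 and raise a warning. N is
taken as the class count (consistent with per-class summation), a choice
the formulas leave open. Count concordance between automated and manual
per-image counts is the standard coefficient of determination R², with
predicted counts treated as estimates of the manual reference; constant
manual counts make R² undefined and are rejected.

## Grad-CAM

The interpretation map for a target class is the rectified weighted sum of
the last convolution block's output channels, each weighted by the spatial
mean of the target logit's gradient with respect to that channel, then
upsampled to the patch size (nearest-neighbour by default — no
interpolation artifacts in tests — bilinear optionally). In this
architecture everything after the last block is GAP + affine, so that
gradient is exactly `W_head[k, c] / S` at every position; the
implementation uses this closed form, verified in the tests against the
single-filter analytic case. Maps are non-negative by construction and
invariant to logit shifts.

## Random-forest baseline

The baseline mirrors classical object-classification tools: a seeded
scikit-learn random forest (default 100 trees, majority vote) on
pre-defined features of each region — area/volume, equivalent diameter,
interior mean, variance and quantiles (10/25/50/75/90), exterior-ring mean
(3-voxel dilation), and optionally the centroid coordinates
(`include_spatial`). Because the exact feature set of any particular
external tool is not reproduced, cross-method comparisons are stated as
bounds (forest ≤ some accuracy, CNN ≥ some accuracy), not as exact scores.

## Synthetic scenes

All generators are pure functions of their parameters and seed, and each
scene ships image, mask and full ground truth.

- **Gray-level cells** (`gen_cells`): non-overlapping disks (rejection
  sampling with a retry cap; failure reports the achieved count) on a zero
  background; class A interiors have mean 80, class B 180, i.i.d. Gaussian
  pixel noise sd 5 — a 100-level gap at 20× the noise, the regime where
  intensity alone should solve the task. Radii are drawn narrowly (6–8) so
  that average gray level is the sole class-discriminating factor and
  object scale stays a minor nuisance: with a global-average-pool head,
  wide radius variation would make area × intensity a latent confounder of
  the intensity rule, which is not the phenomenon this scene isolates.
  Options: per-cell mean jitter (`cell_sd`) and a left/right class split
  (`spatial_split`).
- **Oriented textures** (`gen_oriented_textures`): a grid of tiles, each
  filled with white noise smoothed by an elongated Gaussian kernel rotated
  to the tile's class angle (0° vs 90° by default), then affinely
  standardized per tile to a common mean and variance. First and second
  moments are matched across classes *exactly* by construction; only
  orientation separates them. The synthesis method (oriented smoothing of
  white noise) is this package's choice — moments and orientation are the
  constraints honored. A brute-force oriented-gradient-energy statistic
  separates the classes perfectly (the tests' sanity oracle) while
  per-tile moments do not.
- **Granular textures** (`gen_granular_textures`): isotropic variant where
  the classes differ only in correlation length (fine vs coarse smoothing,
  moments again matched). Marginal pixel statistics — mean, variance,
  quantiles — are class-blind; only the spatial autocorrelation differs,
  a feature that is rotation invariant and absent from pixel-wise
  pre-defined feature sets. With `spatial_split` the grid's left half is
  class 1 and right half class 2.
- **3D blobs** (`gen_blobs3d`): ellipsoids in a volume, classes differing
  by mean intensity or axis ratio; exercises the volumetric code path
  (3D convolutions, multi-page TIFFs, 3D features) at desk scale.

None of the generators attempts to imitate real microscopy point-spread
functions, staining variability or specific tissue appearance. Passing the
benchmarks therefore demonstrates that the pipeline recovers the intended
discriminating feature from few labels under controlled conditions — not
that any particular accuracy transfers to real data.

## Benchmark protocols

Three protocols wire the full annotate → train → predict cycle
(`segpatch.benchmarks`), sized to run in seconds to minutes on one CPU:

1. **Cells**: 100 disks, 10 labels (5 per class, stratified), patch 24²
   (~1.5× the largest disk diameter, limiting how many neighbours enter a
   crop), normalization `none` with the 1/255 global scale (see
   normalization rationale above), depth 3 / width 32, 300 epochs.
   Held-out accuracy on the 90 unlabeled objects is 1.0 across seeds.
2. **Textures**: 150 tiles at 0°/90°, 45 uniformly sampled labels, patch =
   tile = 32², per-patch min-max, no augmentation, 300 epochs. Held-out
   accuracy on the 105 remaining tiles is 1.0 across seeds, while the
   pre-defined-feature forest stays near chance — no feature in its set
   encodes orientation.
3. **Confounding demonstration**: granular-texture grid with the left/right
   class split. The forest given centroid features learns the spatial
   shortcut (its content features are class-blind here): near-perfect on
   the original layout, collapsing to chance on an exactly 90°-rotated
   copy of the scene. The CNN trained with rotation augmentation (flips,
   rot90, free-angle) relies on the rotation-invariant granularity feature
   and keeps its accuracy on the rotated copy. This illustrates the
   confounding-variable failure mode of location-aware features and the
   value of augmentation for building invariances in.

Training length (300 epochs) and scene sizes are the package's desk-scale
defaults for these protocols; the config default remains 600 epochs.

## Known limitations

- No resampling to isotropic voxel spacing; anisotropic 3D data is cropped
  as stored.
- Objects larger than the patch are truncated, not rescaled.
- No early stopping, mixed precision or fine-tuning of large pre-trained
  backbones; the numpy implementation targets small models and datasets
  (thousands of parameters, up to a few thousand patches), not large-scale
  training.
- Free-angle rotation augmentation interpolates the mask channel bilinearly
  (consistent with the intensity channels) rather than re-binarizing it.
- Uncertainty-driven (entropy-based) annotation sampling is intentionally
  out of scope; sampling is uniform or manual, and corrections are
  explicit.
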