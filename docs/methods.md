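# Methods

## Model

The network maps an RGB image `3×S×S` (S divisible by 32) to a
foreground-probability map `1×S×S` through a five-level encoder–decoder.

**Encoder.** A ResNet50-style trunk reduced to its convolutional part. The
first downsampling unit is a 7×7 stride-2 convolution (BN, ReLU) followed by
3×3/stride-2 max pooling; the classifier's average-pooling and
fully-connected layers are absent. Units 2–5 are bottleneck stages of
3, 4, 6 and 3 residual blocks with output channels 256, 512, 1024, 2048 and
bottleneck widths 64, 128, 256, 512. Each block computes
`ReLU(residual(x) + shortcut(x))` where the residual path is
1×1 → BN → ReLU → 3×3 → BN → ReLU → 1×1 → BN; the shortcut is the identity
when shape is preserved and a strided 1×1 convolution + BN otherwise.
Downsampling stride sits on the first block of stages 3–5 (on the 3×3
convolution); stage 2 keeps the post-pool resolution. At S = 256 the stage
outputs are 64×128×128 (pre-pool), 64×64×64, 256×64×64, 512×32×32,
1024×16×16 and 2048×8×8.

**Decoder.** Four upsampling units, each: bilinear 2× upsample →
concatenate encoder skip → 1×1 convolution (channel reduction) → 3×3
convolution → BN → ReLU → 3×3 atrous convolution (dilation d, padding d) →
BN → ReLU → squeeze-and-excitation. The skip sources are the stage-4/3/2
outputs and the **pre-pool** 7×7-conv map: U-Net-style concatenation with
exactly these sources is the only fusion consistent with the decoder
output plan (1024×16×16, 512×32×32, 256×64×64, 64×128×128), and the
64×128×128 stage has no post-pool encoder counterpart to pair with. Concatenated unit inputs are therefore 3072/1536/768/320
channels, reduced by the unit's 1×1 convolution to 1024/512/256/64. The
head is bilinear 2× upsample → 1×1 convolution to one channel → sigmoid.
All convolutions are padded to preserve spatial size (stride aside); no
transposed convolutions are used anywhere (checkerboard artifacts).

**Squeeze-and-excitation.** Squeeze is a per-channel global average pool;
excitation is FC `C → ⌊C/R⌋` (floored, clamped to ≥ 1), ReLU, FC back to
`C`, sigmoid; the resulting per-channel weights in (0,1) rescale the map.
Default R = 6, the ratio at which this architecture segments best in
comparative runs over R ∈ {4, 6, 8, 10}. The FC layers carry biases (the
common convention).

**Receptive field.** The package's `receptive_field(k, d)` implements
v = (k+1)(d−1) + k — the convention this architecture standardizes on,
which counts a dilated 3×3, d = 2 kernel as covering a 7×7 field. The
conventional effective-kernel size k + (k−1)(d−1) (which gives 5 for that
case) is deliberately exposed under the separate name
`effective_kernel_size` so the two conventions cannot be confused.

**Width multiplier.** Every channel count is scaled by `width_multiplier`
(rounded, clamped to ≥ 1). Topology, strides and spatial sizes are
unchanged, giving a faithful desk-scale variant (1/8 width) for CPU runs.

**Initialization.** Without pretrained weights: He fan-in normal for
convolution/linear weights, zero biases, BN scale 1 / shift 0, from a fixed
seed. An encoder trained elsewhere can be loaded from an `.npz` archive by
parameter name + shape (`load_pretrained_encoder`), which returns a
matched/missing/unexpected report; transfer requires the full-width
encoder, since at any other width no shape can match.

**Bilinear upsampling** uses the half-pixel (corners-not-aligned)
convention, implemented as exact separable interpolation matrices; the
adjoint of the same matrices is the gradient.

## Autodiff core

`wbcseg.nn` is a reverse-mode automatic-differentiation layer over NumPy
float32 arrays, scoped to the operator set this network needs: elementwise
arithmetic and activations, reductions, concatenation, conv2d (stride,
padding, dilation; im2col with a fast 1×1 path), 3×3 max pooling, batch
normalization (batch statistics in training, running statistics — unbiased
variance, momentum 0.1 — in eval), global average pooling, fully-connected
layers, exact 2× bilinear upsampling, and Adam (β = 0.9/0.999, ε = 1e-8).
Backward passes are hand-written and tested against scipy correlations,
naive reference formulas and finite differences.

## Losses

BCE is the pixel mean of −[y log p + (1−y) log(1−p)]. The focal loss uses
per-pixel terms −α(1−p)^γ log p (foreground) and −(1−α)p^γ log(1−p)
(background), with defaults α = 0.25, γ = 2, and is likewise averaged over
pixels — the mean reduction matches the BCE normalization and makes the
γ = 0, α = 0.5 case reduce exactly to BCE/2 (a tested identity). Probabilities are clamped to
[1e-7, 1 − 1e-7] before logarithms so saturated sigmoid outputs stay
finite; the clamp passes no gradient outside the interval.

## Metrics

Dice, foreground IoU, PPV and sensitivity are pixel-set ratios (prediction
A, ground truth B; PPV divides by |A|, sensitivity by |B|). "mIOU" is the
single-foreground IoU averaged over images — no class mean exists in a
binary task. The Hausdorff distance is implemented exactly as the directed
form max_{a∈A} min_{b∈B} ‖a−b‖ (scipy's `directed_hausdorff`), in pixels;
a symmetric variant is exposed separately. Conventions: ratio metrics are
1 when both masks are empty and 0 when exactly one is; the directed HD
raises on an empty mask, and the dataset aggregator substitutes 0 (both
empty) or the image diagonal (one empty) so reports stay finite. Dataset
values are arithmetic means of per-image values. Metrics are computed on
postprocessed predictions.

## Postprocessing

Thresholding at 0.5 (p ≥ t convention), then: 8-connected foreground
components with area < 64 px removed; 4-connected background components not
touching the border with area ≤ 64 px filled. The source names only
"mathematical morphology" with no operations or sizes, so cleanup is
area-filtering + hole-filling (idempotent by construction) rather than a
literal open/close sequence; connectivities follow the standard
foreground/background duality and all values are configurable. The 64 px
defaults are small relative to any plausible cell (the default generator's
smallest cell covers ≈ 7% of a 256² canvas ≈ 4600 px).

## Synthetic data

The generator emulates the stated difficulty factors of single-WBC crops:

* **Geometry** — one star-convex cell per image: an ellipse with semi-axes
  uniform in 0.15–0.35 of the side, modulated radially by zero-mean random
  harmonics (orders 2–5) scaled by `boundary_irregularity` (default 0.15)
  and normalized so the enclosed area stays at the ellipse's; 1–3 darker
  elliptical nucleus lobes inside. The mask is the exact pre-blur cell
  support, so ground truth is unambiguous at blurred boundaries.
* **Color similarity** — the cytoplasm color sits at RGB distance
  `color_proximity` from the background color (default 0.25; 0.05–0.1
  emulates lymphocyte/monocyte difficulty). Lowering it provably lowers
  the intensity step across the mask boundary (a tested property).
* **Uneven brightness** — a smooth multiplicative field in 0.85–1.15.
* **Blur** — Gaussian, σ = 1.5 px, after compositing.
* Weak smooth background texture and finer cytoplasm granularity are
  contrast-independent, mimicking stain texture.

Everything is a pure function of the seed. What the generator does *not*
model: multi-cell scenes, red-cell/platelet distractors, stain-specific
color chemistry, camera noise, or the full shape taxonomy of the five WBC
types. Passing tests therefore demonstrate that the architecture, losses
and pipeline work as specified and can recover cell boundaries under
color-proximity/brightness/blur nuisance — not clinical-grade accuracy on
real smears.

**Augmentation** applies rotation (±180°), horizontal/vertical flips,
scaling (0.8–1.2), brightness and contrast (±20%); the op families are
fixed, the ranges are this package's defaults. Geometric ops
use bilinear resampling for the image and nearest-neighbour for the mask
(kept strictly binary); exact multiples of 90° rotate losslessly.
`expand_dataset` grows a source set to a target size by seeded round-robin
augmentation with per-item provenance. `split_dataset` shuffles by seed and
partitions 8:1:1 with floor-then-distribute rounding. The CLI's `synth`
splits *sources* first and expands within each split, which is stricter
than expanding before splitting: augmented variants of one source can never
leak across the train/test boundary.

## Training protocol

Full-scale defaults: Adam, lr 1e-4, batch 8, 200 epochs; BCE for clear-boundary datasets, focal loss for hard-sample
ones. No learning-rate schedule and no early stopping; the checkpoint with
the best validation Dice is kept (this package's model-selection
convention). Non-finite loss aborts with a diagnostic. Runs are
deterministic given the config and seeds.

The **desk profile** — width 1/8, side 64, 200 synthetic images (8:1:1),
≤ 20 epochs — uses lr 1e-3: the full-scale rate of 1e-4 is matched to
200-epoch schedules, and a far shorter schedule takes a proportionally
larger step. On one CPU core the profile trains in about a minute and
reaches ≈ 0.97 held-out Dice on default scenes (≈ 0.90 with the focal loss
on hard low-proximity scenes); these numbers are recomputed by the test
suite, not quoted from anywhere.

## Numerical choices and edge cases

* float32 throughout; losses on plain arrays are computed in float64.
* BN uses ε = 1e-5; training-mode variance is computed in one fused pass
  and clamped at 0 against cancellation.
* Binarization uses the inclusive p ≥ t convention (an all-0.5 map at
  t = 0.5 is foreground).
* The SE bottleneck width is ⌊C/R⌋ clamped to ≥ 1, so the block is valid
  even when C < R.
* `split_dataset` requires at least as many items as partitions;
  `expand_dataset` requires a non-empty source set and target ≥ source.
* Checkpoints are `.npz` parameter/buffer archives with a JSON sidecar
  carrying the network configuration.

## Known limitations

* CPU-only and NumPy-bound: full-width 256² training at the reference
  protocol is possible but slow; the package is designed to demonstrate
  and test the method at desk scale.
* Single-cell scenes only; no watershed separation of touching cells.
* The default receptive-field rule is larger than the standard
  dilated-kernel extent (7 vs 5 for a 3×3 kernel at d = 2); both
  conventions are exposed, and the discrepancy is documented rather than
  resolved.
* Synthetic difficulty is a proxy; no claim transfers to real smear data
  without retraining and validation on real annotated images.
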