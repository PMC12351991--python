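# Methods

This note documents the models and procedures the package implements, the
defaults it ships with, and the design choices made where the design was
genuinely open.

## The segmentation model

ES-UNet is a 3D encoder–decoder for binary semantic segmentation of
volumetric medical images (the motivating regime is co-registered PET/CT
tumour delineation: a two-channel input, a small foreground fraction, and
irregular lesion boundaries).

**Encoder.** N = 4 levels. Block 1 applies no pooling; blocks 2..N each
start with a 2×2×2 max pool (stride 2). Every block is two (3×3×3 conv →
batch norm → ReLU) units. Channels double per level: level i has
2^(i−1)·`base_channels`; an input of (C₀, D, H, W) therefore yields a
deepest feature map of (8·`base_channels`, D/8, H/8, W/8). Spatial
dimensions must be divisible by 2^(N−1).

**Full-scale skip connections.** Decoder level j receives one path from
every encoder level i ≤ j and every deeper decoder level i > j — N paths per
decoder in the full variant. Each path normalises its payload to
`path_channels` (C) channels at level-j resolution:

| route | operations |
| --- | --- |
| encoder, i < j | channel attention → max-pool 2^(j−i) → conv3 → BN → ReLU |
| encoder, i = j | channel attention → conv3 ×2 → conv1, each + BN + ReLU |
| decoder, i = j+1 | transposed conv 2³ stride 2 (bare) → conv3 → BN → ReLU |
| decoder, i > j+1 | trilinear ×2^(i−j) → conv3 → BN → ReLU |

Channel attention (squeeze-and-excitation: global average pool → bottleneck
→ sigmoid gate) sits on every encoder-to-decoder path, including the
same-level one, and never on decoder-to-decoder paths. The bottleneck width
is round(0.25·C), floored at 1. The decoder block concatenates its paths and
fuses them with a 3×3×3 conv whose output width is standardised to
(paths·C).

**Deep supervision.** Each decoder level carries an auxiliary head:
1×1×1 conv to one channel → trilinear upsampling by 2^(j−1) to input
resolution → sigmoid. The final prediction is the equally weighted
arithmetic mean of all head outputs; training applies the full loss to every
head and averages (the same equal weighting as the fusion rule — the loss
aggregation was an open choice and mirroring the fusion is the simplest
consistent one). Masks are produced by thresholding the fused map at 0.5
with ties (probability exactly at threshold) going to foreground.

**Ablation variants.** `base` keeps only the same-level encoder path plus
the adjacent up path; `enc_only` adds the cross-scale encoder paths;
`dec_only` adds the cross-scale decoder paths; `both` is the full topology.
Path plumbing for the restricted variants keeps the (paths·C) output-width
rule, so head sizes scale with the topology.

## Region Specific Scaling (RSS)

A label-aware geometric augmentation. For one axis: find the global
inclusive min/max indices of nonzero label voxels over the whole volume
(never slice-wise, so multiple lesions are spanned jointly); split the
volume into the slab between those bounds and the two outer slabs; resample
the middle slab (image channels trilinear, label nearest) along that axis by
a ratio r drawn uniformly from [r₁, r₂] = [2/3, 3/2]; reattach the outer
slabs untouched. If the assembly is now short, it is re-centred and both
ends are mirror-padded (reflect, without repeating the edge voxel; an odd
remainder pads the low-index end). If it is long, the excess is cropped
symmetrically (odd remainder off the high-index end). Output shape always
equals input shape.

Axes are visited sequentially in the fixed order (depth, height, width),
each selected independently with probability p = 1 − (1 − 0.5)^(1/3) ≈
0.2063, so the chance that at least one axis is transformed is 0.5. Bounds
are recomputed immediately before each axis's transform (sequential
semantics). An empty label makes the transform a logged no-op.

Open choices made here: the ratio distribution (a single uniform draw over
[r₁, r₂]; a fair-coin split between the reduction and enlargement intervals
is available behind `RSSConfig.split_draw`), the padding/cropping side
conventions, and the augmentation order mirror → rotate → RSS.

## Dynamically Weighted Dice (DWD) loss

With soft precision and recall coefficients C_P = Σyp/Σp² and
C_R = Σyp/Σy², and weights w_P = 1 − (C_P − C_R), w_R = 1 − (C_R − C_P)
(so w_P + w_R = 2):

    L_DWD = 1 − 2Σyp / (w_R·Σy² + w_P·Σp² + ε).

This **narrative pairing** (w_R on Σy², w_P on Σp²) is the default because
it is the one that magnifies the loss under a precision/recall disparity and
penalises the weaker side more strongly: the denominator difference from
plain Dice is −(C_R − C_P)²·Σyp/(C_P·C_R) ≤ 0. The opposite **as-printed
pairing** (w_P on Σy²) provably shrinks the loss under disparity; it is
implemented behind `LossConfig(pairing="as_printed")` and its ≤-Dice
behaviour is asserted in the tests to document the discrepancy. When
C_P = C_R both weights are 1 and DWD equals Dice exactly.

With soft predictions the coefficients can exceed 1 (y=[1], p=[0.5] gives
C_P = 2), making a raw weight negative and the loss unbounded; weights are
clipped to [0, 2], which is inactive in the equal-coefficient regime and
preserves the degenerate-to-Dice property.

The total objective is mean focal loss over voxels (focusing exponent
γ = 2) plus α·DWD with α = 1; every ratio denominator carries ε = 1e−6.
During training the DWD weights are treated as constants of the current
state — recomputed every step but not differentiated through. The dynamic
weighting is a per-step reshaping of the loss landscape; backpropagating
through the weights would add a second-order term the loss's description
does not call for, and holding them fixed keeps the gradient simple and
verifiable against finite differences (the tests do exactly that).

Losses are computed per sample over the flattened volume, then averaged
over the batch (batch size 1 by default).

## Metrics

DSC = 2|∩|/(|Ŷ|+|Y|), IoU = |∩|/|∪|, VOE = 1 − IoU, always on whole 3-D
volumes. Two empty masks score DSC = IoU = 1 and VOE = 0 (correctly
predicting absence), flagged in the record. Dataset-level numbers are means
over cases, not pooled over voxels.

## Training procedure

Adam with betas (0.9, 0.99), no weight decay; cosine annealing with warm
restarts, lr from 1e−3 to 1e−5 with a 25-epoch restart period over 100
epochs (defaults; the schedule is evaluated at fractional epochs per step).
Cases are split with a floor-based hold-out: n_val = floor(0.2·n) — the rule
that yields (180, 44) from 224 cases, (16, 4) from 20 and (33, 8) from 41.
Augmentation per step: mirroring with probability 0.5 along a random axis,
rotation by a uniform angle in ±15° about each of the three axes in fixed
order, then RSS. The best-validation-DSC weights (and batch-norm running
statistics) are what `train` returns. Everything derives from one integer
seed: splitting, augmentation, and weight initialisation (He fan-in normal).

## The numerical substrate

No GPU framework is part of the stack: layers (3D convolution via
im2col + BLAS matmul, max pooling, transposed convolution, trilinear
upsampling with explicit interpolation matrices, batch normalisation,
squeeze-and-excitation attention) carry hand-written forward/backward passes
in float32, verified against central finite differences in the unit tests.
Two deliberate deviations from the textbook blocks: convolutions feeding
batch norm have no bias term (batch norm cancels it exactly, leaving a
parameter with identically zero gradient), and the attention bottleneck uses
a leaky activation (slope 0.01) so a one-unit bottleneck cannot start
gradient-dead. Batch statistics with batch size 1 reduce to per-channel
spatial statistics; running estimates serve evaluation mode.

The transposed-convolution path maps its input directly to C channels
before the subsequent 3×3×3 conv (rather than preserving its input width);
both readings satisfy "adjust the channels to C" and the narrower one costs
a fraction of the compute at full resolution.

## Synthetic phantoms

The generator emulates the data regime, not the physics: a structure channel
of two-to-three nested-ellipsoid intensity plateaus plus Gaussian noise, an
uptake channel with a smooth elevated profile inside each lesion
(mean elevation ≈ the configured contrast, default 6 over a background of
1, noise sd 1), and lesions as ellipsoids (radii 6–10 voxels in a 64³
volume by default, ≈0.3–1.6% foreground — the class-imbalance band the
losses target) with a low-order quadratic-harmonic radial perturbation
(amplitude 0.25, clipped so the shape stays star-convex and hence
6-connected). Phantoms are deterministic in (spec, seed); suites derive one
RNG stream per case from (seed, index).

What passing on phantoms does **not** show: robustness to scanner noise
characteristics, Hounsfield/SUV calibration, anatomical context, multi-site
variability, or anything about real HECKTOR/MSD performance. The phantoms
verify the machinery — geometry, probabilities, losses, optimisation — at
desk scale.

## Problem sizes used in the checks

The test suite and the acceptance script run CPU-sized problems: toy
networks (base width 2–8) on 16³–32³ volumes, a full-width (base 32)
encoder probe at 64³, a single-case memorisation run (one 32³ phantom,
up to 200 steps, DSC > 0.9 typically reached within ~60 steps), 10,000-draw
frequency estimates, and 1,000-pair identity sweeps. Default configuration
values (base width 32, 100 epochs) describe the intended full-scale regime
and are exercised structurally, not trained to convergence.

## Known limitations

- Binary segmentation only; the dynamic weighting needs per-class design
  work for the multi-class case.
- No Hausdorff/surface metrics, no test-time augmentation, no ensembling,
  no post-processing.
- The CPU substrate is intended for correctness and small studies, not for
  training at 144³ scale.
- Orientation handling canonicalises to RAS on load; exotic affines are
  round-tripped through the stored affine but not otherwise validated.
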