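# Methods

This note records the model as implemented, the parameter calibration, what
the synthetic data do and do not emulate, and the numerical and design
choices that were genuinely open.

## Network

All feature maps are `C × H × W` with `H × W` equal to the input
resolution throughout ("full resolution": stride 1, same padding, no
pooling or upsampling anywhere). Default configuration
(`ModelConfig()`):

| piece | definition | parameters |
|---|---|---|
| stem | 3×3 conv 1→32, BN, ReLU | 384 |
| trunk ×4 | recursive ConvNeXt V2 stage (below) | 4 × 29,488 |
| attention | DWAM + EFF (below) | 70,991 |
| head | 1×1 conv 32→1, sigmoid | 33 |
| total | | **189,360 → 0.19 M** |

One trunk stage: recursive depthwise 7×7 (R = 2) → channelwise LayerNorm
(ε = 1e-6) → recursive standard 3×3, 32→48 → GeLU (exact erf form) → GRN
(stabiliser 1e-6, plus 1e-12 inside the square root so the gradient stays
finite on an all-zero channel) → recursive standard 3×3, 48→32 → residual
add. Without the attention stage the model totals 118,369 → 0.12 M.

**Recursion convention.** `y₁ = conv(x)`, `y_t = conv(x + y_{t−1})`, the
same weights at every iteration — the recurrent-convolution convention of
the vessel-segmentation literature. No extra nonlinearity is inserted
between iterations in the trunk; the stage's own LN/GeLU/GRN sit at their
pipeline positions. Where recursion wraps a channel-changing convolution
(the 32→48 expand and 48→32 project), the previous iterate is matched to
the input width by truncating or zero-padding channels before re-injection;
this projection is parameter-free, so recursion depth provably never
changes the parameter count (asserted in the tests for R ∈ {1, 2, 3}).

**Middle 3×3 convolutions are standard, not separable.** The jump from the
1×1-pointwise stage (≈ 5 k parameters) to the 3×3 stage (≈ 29 k) is only
attainable with full 3×3 channel mixing; separable middle convolutions
would change the count by an order of magnitude.

## Parameter calibration

Three widths are not pinned down by the architecture description and were
calibrated once against the published totals (0.12 M backbone, 0.19 M full
model, both at two decimals, round-half-up):

- `expansion_width = 48` — smallest value in {40, 44, 48, 52, 56, 64} for
  which the 4-stage backbone prints 0.12 M (values: 40 → 0.10, 44 → 0.11,
  48 → 0.12).
- `fc_hidden = 576`, `spatial_mid_channels = 64`, `eag_mid_channels = 32` —
  place the attention stage at 70,991 parameters, the ≈ 0.07 M difference
  between the two published totals.

The attention budget deliberately sits in the **channel-attention MLP**
(which acts on pooled length-32 vectors) rather than in wide spatial
embeddings: widening `fc_hidden` costs O(C·hidden) multiply-adds per image,
whereas widening the spatial embedding multiplies every forward pass's
activation volume by H·W. An earlier calibration with
`spatial_mid_channels = 576` hit the same 0.19 M but ran ~2× slower end to
end and contradicted the design's lightweight premise; `fc_hidden = C`
("no reduction ratio") was given up in its favour.

## DWAM and EFF details

- The pooled descriptor combines the 5×5 and dilated branches by
  **elementwise addition** before global average pooling; a `combine:
  concat` flag exists for experimentation.
- Two separate FC heads (hidden→C each) produce the channel gates `a`
  and `a′`; both are sigmoids, so gates are strictly inside (0, 1) in exact
  arithmetic (float32 can round a saturated gate to 1.0; the bound tests
  therefore run with batch statistics active, which keeps logits moderate).
- With every weight and bias zeroed, the channel block traces by hand to
  `FG = 0`, MLP output 0, gates exactly 0.5, and zero gated output — this
  trace is frozen in the tests.
- Spatial gates `β`, `β′` are single-channel and broadcast across the
  embedding channels; the fusion convolution is 1×1 (`final_kernel`
  configurable).
- The dilated branch uses rate 3 (effective receptive field
  `k + (k−1)(d−1) = 7`) and is not recursive; the 3×3 and 5×5 branches are
  recursive with R = 2.
- EFF: `fused = x_att + EAG(x_att, x_skip) ⊗ x_skip`, then the ECA channel
  gate (3-tap 1-D convolution over the pooled descriptor, no bias), then
  the SA spatial gate (7×7 convolution over channel-mean and channel-max
  maps). Forcing all gates to one reduces the stage to `x_att + x_skip`
  (diagnostic flag, used by the tests).
- DWAM + EFF are inserted once, after the trunk, with the trunk output as
  the skip path.

## Loss and metrics

Soft Dice loss per the formula above, evaluated as one graph primitive in
float64 as `(denom − numer)/denom`; this keeps a near-perfect prediction's
loss (ε / 2|X| ≈ 5e-8 at |X| = 100) exact where float32 subtraction would
cancel. The ε placement follows the printed formula literally, including
its value of exactly 0.5 when prediction and target are both empty; a
`strict_empty` mode returning 0 exists but is off by default. Hard metrics
threshold at 0.5 with ties to foreground and are reported both micro
(pooled pixels) and as per-image means, since the choice of aggregation is
a genuine ambiguity.

## Training

Adam (β = 0.9/0.999), learning rate 1e-4, batch 32, up to 200 epochs with
early stopping after 100 epochs without validation improvement — these
defaults mirror the published training protocol; "improvement" means
exceeding the best monitor by more than 1e-6. The monitored quantity
defaults to validation pixel accuracy and can be switched to Dice. The
best-epoch checkpoint is the one kept. Weight initialisation
(Kaiming-uniform, zero biases, zero GRN gain/bias), shuffling and
augmentation all derive from explicit seeds; two runs with the same seeds
are bit-identical on one machine.

Augmentation (probability 0.5 per op): rotation ±15°, Gaussian noise
σ = 0.02 of the dynamic range, unsharp-mask sharpness in [0.5, 2],
horizontal/vertical flips and a diagonal flip (transpose). Geometric ops
hit image and mask identically — bilinear for the image, nearest-neighbour
for the mask, which therefore stays binary; photometric ops touch the image
only. Per-image standardisation to zero mean/unit variance precedes the
network (constant images map to zero; the operation is not idempotent and
is applied exactly once).

## Synthetic angiograms

The generator emulates the statistical character of en-face OCTA: bright
branching trees over dark speckle. Trees grow as seeded random walks from
the image border inward (unit steps, heading jitter ±14°/step, branch
probability 0.07/step, calibre 6 px at the root shrinking by ×0.72 per
branching, floored at 1 px), stamped as disks with a 0.75 px minimum radius
so even 1-px branches rasterise 8-connected. Rendering: multiplicative
speckle over a dark base (σ = 0.35), smooth capillary texture, Gaussian-
blurred vessel signal (gain 0.55), additive noise, clipped to [0, 1]. All
randomness flows through counter-based Philox streams keyed by
`(seed, sample index)`, so datasets are byte-reproducible across platforms.

At the default 304×304 configuration, foreground coverage over 20 seeds
spans ≈ 9–17% (within the 5–20% band typical of vessel maps) and vessels
are ≥ 0.2 brighter than background on average. What the generator does
*not* model: physical OCT speckle statistics, the foveal avascular zone,
projection artifacts, pathology. Passing the learning tests therefore
demonstrates that the network can learn tree-like curvilinear structure
from realistic-looking contrast — not clinical performance.

## Problem sizes used by the test suite

The engine is pure numpy on one CPU, so the self-contained checks run at
reduced scale, chosen once: the learning-capability test trains the full
default model on 80 angiograms at 32×32 (calibre scaled to width_root 3)
for 12 epochs at learning rate 1e-3, batch 8, five seeds, and requires
held-out soft Dice ≥ 0.85 in at least four of them; the end-to-end pipeline
check uses 12 samples at 16×16 for 2 epochs. Architectural and
parameter-count checks are exact and scale-free.

## Numerical choices

- float32 throughout the network; reductions inside the Dice loss in
  float64.
- Standard convolutions evaluate tap-by-tap as batched BLAS matmuls (a 1×1
  convolution is a single gemm); depthwise convolutions run in the Fourier
  domain with FFT size H+span−1, where circular and linear results
  coincide exactly, including both gradients.
- Batch norm: ε = 1e-5, momentum 0.1, batch statistics in training and
  running statistics at inference. Note a batch of one makes the
  normalised activations identically zero and nulls upstream gradients —
  training should use batches ≥ 2.
- LayerNorm acts channelwise per spatial position (ConvNeXt convention).
- Checkpoints are single `.npz` files holding weights, normalisation
  buffers, and the JSON-encoded model configuration.

## Known limitations

- No GPU path and no mixed precision; throughput is roughly 1 s per
  training step on 8 × 32×32 images, so full-scale (304×304, 200-epoch)
  training is out of reach of this implementation — it targets method
  study, not production training runs.
- The channel-matching rule inside recursive channel-changing convolutions
  is one reasonable convention among several; alternatives (e.g. recursing
  only the depthwise convolution) would change outputs but not counts.
- The head defaults to 1×1; an 11×11 head is supported as a configuration
  option and changes the total by < 0.01 M.
- Batch-dependent metrics: evaluation always runs per image in eval mode,
  so reported Dice/accuracy do not depend on batch composition.
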