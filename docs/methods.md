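# Methods

This note documents the models, numerical choices and design decisions
behind the package, and what the synthetic experiments do and do not show.

## Network topology

The segmentation model is an encoder–bridge–decoder network of depth four
(three encoder stages plus a bridge; three stride-2 downsamplings in
total, so input extents must be divisible by 8). Default widths are
68/136/272 (encoder), 544 (bridge), 136/68/68 (decoder) with a final 34
before the 1×1 output head — the full-size configuration. Every encoder
stage is a residual block: two 3×3 convolutions (the first carrying the
stride) with batch normalization and ReLU, plus a 1×1 stride-matched
projection with batch norm on the shortcut and the final ReLU after the
addition. Convolutions keep their bias terms even when followed by batch
norm, matching common framework practice.

Attention placement: channel attention after each encoder stage (gating
the features offered both to the skip and to the next stage), CBAM
(channel then spatial attention) after the bridge block, spatial
attention on each decoder stage's upsampled features, and an additive
attention gate (SCAG) on each skip connection, driven by the
pre-upsampling deep features (bridge output for the deepest skip, then
each decoder stage's output).

### Decoder channel wiring

The published layer table fixes the widths of the decoder's 3×3
convolutions but not the transposed-convolution output channels. We use
2×2, stride-2 transposed convolutions that halve the incoming deep
channels (544→272, 136→68); at the final stage the upsample keeps its 68
channels and the channel reduction is deferred to the last 3×3
convolution (68→34), which is why that stage's two convolutions have
asymmetric widths. This wiring was selected by matching the model's
aggregate accounting: it yields 7,771,710 trainable parameters (7.77 M)
and 132.27 GMac for a 512×512×3 forward pass under the MAC convention
below — the compute figure agrees with the reference total for this
architecture to within 0.1 %, the parameter total to within 0.8 %. No
wiring consistent with the published description (residual blocks in the
encoder only, the stated attention parameterizations) reproduces the
reference parameter total exactly; the residual ~0.06 M is unattributed
and we report our true count.

### MAC convention

`count_macs` counts `kernel_elements × c_in × c_out × output_positions`
for every convolution, transposed convolution (also at its output
resolution) and linear map, including those inside attention operators.
Normalization, activations, pooling and element-wise gating are free.
This is the convention of the common profiler tools; batch 1, input
512×512×3.

## Attention operators

* Channel attention: hidden width exactly c/2, shared bias-free MLP over
  the global max- and average-pooled descriptors, sigmoid of the summed
  branch outputs. Odd c is rejected at construction unless an explicit
  hidden width is given.
* Spatial attention: 7×7 convolution (zero padding 3, stride 1, no bias)
  over the 2-channel concatenation of channel-wise max and mean maps.
* SCAG: the shallow 1×1 projection is stride-2 and bias-free; the gate
  projection and the 1-channel reduction carry biases. The attention map
  is computed at the gate resolution and bilinearly upsampled
  (half-pixel centers) back to the skip resolution. With zero-valued
  parameters every gate is exactly 0.5 in float32 (and CBAM exactly
  0.25), which the tests use as an algebraic anchor.
* No normalization layers inside attention operators.

## Numerical core

The package carries its own reverse-mode autodiff over numpy arrays
(`manet.nn`): convolution as an im2col GEMM with channel-major (K, N)
column layout, zero-padding folded into the JIT-compiled gather/scatter
kernels (numba when available, numpy slicing otherwise), fused
batch-norm statistics/normalization/backward passes, and
kernel-equals-stride transposed convolution. All activations are float32;
batch-norm statistics accumulate in float64. Gradients of every operator
are verified against central differences in the test suite at 1e-5
relative tolerance. Interior graph buffers are released as backward
propagation consumes them, keeping peak memory of a training step on the
reduced model near 0.6 GB.

Weight initialization is Kaiming-uniform in its leaky-ReLU (a = √5)
flavor — bound 1/√fan_in, the standard convolution default in the major
frameworks — with zero biases, unit batch-norm scales, all drawn from a
single seeded generator in construction order. Under batch normalization
the effective Adam step scales inversely with weight norm, so this
choice also sets the effective learning rate of the fixed 1e-4 protocol.

## Training protocol

Soft Dice loss with smoothing s = 1 over probabilities (not thresholded),
averaged over the batch and the foreground channels: with the 3-channel
head {background, liver, tumor} the background channel is excluded from
the loss average (its complement is fully determined by the foreground),
which concentrates the gradient on the classes of interest; a 1-channel
head is all foreground. Phantom data has no liver labels, so the middle
channel trains toward empty. Adam (β = 0.9/0.999, ε = 1e-8), initial
rate 1e-4, ×0.1 every 30 epochs, batch 4, 80 epochs at full scale.
Real-time augmentation applies, with probability 0.5 each, a vertical
flip and a shift(±10 %)/scale(±10 %)/rotate(±15°) transform, identically
to image and mask (nearest-neighbour for the mask). There is no
validation split; the kept checkpoint maximizes test-set Dice over
epochs — optimistic selection, reproduced deliberately as part of the
protocol and flagged in the README.

Training is bit-for-bit reproducible on CPU for a fixed seed: weights,
batch order and augmentation draws all derive from seeded generators,
and the numerical kernels are deterministic.

## Preprocessing

CT slices are clipped to the [−150, 250] HU soft-tissue window
(idempotent), globally histogram-equalized over 256 bins and min–max
normalized to [0, 1]; constant slices map to zeros. Grayscale slices are
replicated into the 3-channel input layout. Slice selection keeps slices
with ≥ 1 tumor pixel (threshold configurable). Splits are random 4:1,
seeded; volume mode assigns whole volumes to one side (zero leakage by
construction).

## Metrics

Overlap metrics derive from exact integer confusion counts. Undefined
ratios are reported as NaN and excluded from aggregation rather than
coerced to zero; both-empty pairs count as perfect overlap (Dice =
Jaccard = 1) with ASSD undefined; a tumor-bearing truth with an empty
prediction scores Dice 0 and is flagged as a non-segmentation. ASSD uses
4-connectivity boundaries (image border counts as background), exact
Euclidean distance transforms, pixel units by default and millimetres
when a spacing is attached; volume mode pools confusion counts and
per-slice 2-D boundaries per volume before computing the metrics
(surfaces are not meshed in 3-D). Standard deviations are population
(ddof = 0). The network's sigmoid output is binarized at 0.5 on the
tumor channel.

## Synthetic phantoms

Each phantom slice is an elliptical "liver" (≈60 HU) on a ≈−100 HU
background carrying 0–k disc "tumors" at liver-minus-contrast intensity,
with Gaussian-blurred edges and additive Gaussian noise; masks mark the
pre-blur tumor supports. Defaults: 96×96 px, contrast 45 HU, blur σ 1.5
px, noise σ 10 HU, 1–3 tumors of radius 3–12 px, 20 slices per volume,
0.7×0.7 mm spacing written to the NIfTI headers (exercising the
millimetre ASSD path). Tumor count and radius are uniform draws;
positions are rejection-sampled fully inside the organ.

The phantoms emulate the *structure* of the task — a bright organ with
hypodense lesions of variable count and size, fuzzy boundaries, noise —
but none of the appearance statistics of real contrast CT: no texture,
no neighbouring organs, no partial-volume or acquisition artifacts, no
inter-scanner variability. Passing the phantom experiments therefore
demonstrates that the architecture, losses, metrics and training loop
are implemented correctly and can learn this class of segmentation
problem; it does not certify clinical-grade performance on patient data.

## Experiment scales

CPU-sized experiments use the quarter-width reduction (encoder widths
[17, 34, 68], bridge 136, ≈0.49 M parameters). Odd widths are normally
rejected (attention hidden widths c/2 must be integral); the reduced
configuration opts out via `strict_even=False`, flooring the halved
widths (17 → 8). The end-to-end benchmark trains this model on 200
phantom slices (4:1 split) for 15 epochs and reaches a best test Dice of
≈0.8 per seed (median over three seeds asserted ≥ 0.70 in the acceptance
suite); one seed takes roughly five minutes on a single CPU core. The
ablation harness builds all eight architecture variants (plain U-Net,
residual backbone, each single attention mechanism, all-attention
without residuals, and the full model), verifies the parameter-count
ordering at full width and runs scaled phantom training for each.

## Known limitations

* 2-D slices only; no volumetric convolutions or cascaded liver-then-
  tumor inference.
* The full-size model is buildable and countable on CPU, but training it
  at 512² is impractical without GPU acceleration; correctness at full
  scale is established via accounting and shape/trace checks, not
  training.
* The exact reference parameter total is missed by ~0.8 % (see Decoder
  channel wiring); compute agrees to 0.1 %.
* Best-on-test checkpoint selection inflates reported test Dice by
  construction.
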