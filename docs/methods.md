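# Methods

## Model

The segmentation model is a hybrid of a convolutional encoder-decoder and a
patch-token transformer, fused at the bottleneck.

**Local branch.** The encoder is a stride-1 stem (3×3 conv + BN + ReLU)
followed by four stages of basic two-conv residual blocks. The reference
configuration uses depths (3,4,6,3) at widths (64,128,256,512) — a
ResNet-34-like stack. Three stages stride by 2 and the deepest stage keeps
stride 1, so the encoder exposes feature maps at spatial divisors
1/2/4/8 and a 512-channel bottleneck at H/8 × W/8. This resolves a genuine
tension in the architecture description (four encoder stages, but a
bottleneck fixed at one-eighth resolution for fusion): four stages, three
of which downsample.

**Iterative aggregation.** Skip connections are an ordered list of
*aggregation nodes*. A node (f, 2f) upsamples the map at divisor 2f by 2
(bilinear), projects it with a 1×1 convolution to the width of the map at
divisor f, and adds it element-wise. Nodes execute shallow-to-deep in
rounds over the scale set {1,2,4,8} — the default "triangular" plan is
(1,2),(2,4),(4,8),(1,2),(2,4),(1,2) — so later nodes consume earlier
nodes' outputs and deep information percolates to the finest skip through
repeated fusion. An empty plan reduces exactly to plain skip connections,
which is also how the ablation variants 1 and 3 are built. Addition (not
concatenation) is used for every fusion in the network; a concatenating
merge was considered and rejected to keep the parameter budget and the
additive-identity reduction property. The node projections are
**zero-initialised**: every aggregation node starts as an exact additive
identity (a plain skip) and learns how much coarse context to mix in.
Without this, randomly-scaled coarse maps perturb the skips at step 0 and
the aggregated variants start *outside* the plain backbone's function
class, which measurably hurts small-sample training.

**Global branch.** A stride-P convolution with kernel P embeds each of the
N = HW/P² non-overlapping patches as one token of width d (row-major patch
order). Fixed sinusoidal positional encodings over the token index are
added; fixed rather than learned encodings keep the parameter count
independent of image size. Each of the L transformer layers is the
standard pre-norm residual pair x̃ = MSA(LN(x)) + x, x' = MLP(LN(x̃)) + x̃,
with h-head scaled dot-product attention (per-head scale 1/√(d/h), head
outputs concatenated and linearly projected) and a two-layer GELU MLP of
hidden width mlp_ratio·d. The output sequence is reshaped row-major to
(H/P)×(W/P)×d, projected 1×1 to the bottleneck width and bilinearly
resized to H/8×W/8 (an identity when P = 8). Attention is global over all
N tokens; no windowed/shifted attention is used. The 1×1 fusion projection
is zero-initialised for the same reason as the aggregation nodes: the
global branch starts as an additive identity at the bottleneck and learns
its contribution.

**Reference transformer geometry** (P=8, d=512, L=2, h=8, mlp_ratio=4) was
chosen so the token width equals the bottleneck width (no extra projection
needed) and the full model's trainable-parameter count lands at ≈30M
(29.72M exactly; the build log prints it). The count is input-size
independent.

**Decoder and head.** Three ×2 bilinear upsampling stages at widths
(256,128,64); each projects the incoming map and the matching aggregated
skip to the stage width with 1×1 convolutions, adds them, and applies two
3×3 conv+BN+ReLU layers followed by dropout (rate 0.3 — the protocol names
the rate but not the location; after each decoder stage was chosen). A
final 1×1 convolution produces n_classes score channels at full input
resolution; softmax gives per-pixel class probabilities. Multi-class
softmax over {background, A, B} was preferred over two binary heads as the
minimal joint formulation.

**Variants.** 1 = plain backbone; 2 = +aggregation; 3 = +global branch
(plain skips); 4 = full. Variant 4 with an empty plan and a zeroed global
projection reproduces variant 1 logits bit-for-bit given shared weights —
this reduction is asserted in the test suite.

## Training

Smoothed soft-Dice loss with squared denominators, per image and per
foreground class, averaged; ε = 1e-5 appears in numerator and denominator
so that a class absent from both prediction and target contributes 0 loss
(the stability case that motivates the smoothing; ε is otherwise
inconsequential at these problem sizes). Adam with lr 0.001 and default
betas, mini-batch 3, up to 80 epochs, dropout 0.3, per-slice min-max
intensity normalisation to [0,1], random (He/Xavier) initialisation.
Early stopping watches validation loss with patience 10 (the protocol
names the strategy; the patience value is this package's choice), and the
lowest-validation-loss weights are kept. All randomness — init, batch
order, dropout — derives from one seed; identical configs produce
identical training logs. A step-capped mode (`max_steps`, optional
early-exit on a training-Dice target) supports desk-scale experiments.

## Numerical engine

No deep-learning framework is used: `llrhnet.nn` is a small reverse-mode
autodiff engine over numpy arrays. Convolution is lowered to one BLAS
matmul per layer via im2col (slice-copy construction; 1×1 convolutions
bypass im2col entirely), with the transposed forms for the backward pass.
Bilinear resampling is expressed as two 1D interpolation matrix products
(align_corners=False convention), which makes its adjoint exact and
trivial. Batch norm uses batch statistics in training (differentiated
through) and running statistics (momentum 0.1) in inference. Computation
is float32 for training; the oracle tests run the same ops in float64.
Every hand-written vector-Jacobian product is checked against central
finite differences in the test suite.

## Metrics

DC, VOE, RVD, ASSD and HD with exact set semantics on pixel lattices.
Distances are Euclidean between pixel centres, scaled per axis by the
pixel spacing, computed over **all** foreground pixels by default —
faithful to the max/min formulas as written over p∈P, g∈G — with a
boundary-only option (morphological erosion boundary) off by default. The
implementation uses a KD-tree, which is numerically identical to the
O(|P||G|) enumeration (asserted against an independent brute-force oracle
to 1e-9). Conventions for degenerate inputs: DC=1 and VOE=0 when both
masks are empty; RVD undefined for an empty prediction; HD/ASSD undefined
when either mask is empty. Undefined values are reported as NaN with a
reason code, never as silent zeros, so per-class averages are not dragged
down by lesion-free slices. Masks may be 2D slices or 3D stacks: volumes
are processed slice-wise along the anatomical axial axis (derived from the
NIfTI affine) and predicted slices can be restacked into the template
geometry for volume-mode scoring; both slice-mode and volume-mode
evaluation are provided since either convention is defensible for
slice-wise pipelines, with unit spacing as the default.

## Phantom generator

The generator emulates the two structural regimes of the target data, not
their radiological appearance:

* `organ_with_inclusions` — one large smooth blob (class 1) with 2–5
  small inclusions (class 2) strictly inside it; emulates a liver slice
  bearing tumours.
* `scattered_bilateral` — 2–5 small class-1 blobs in the left half with
  class-2 blobs mirrored across the vertical midline; emulates
  co-occurring stroke/WMH lesions and installs a *long-range* cue. The two
  lesion classes share the **same mean intensity** — lesions are easy to
  find but their class is decidable only from the mirrored placement, i.e.
  from context far outside any convolution kernel.

Blob outlines are circles with a randomized low-order radial Fourier
perturbation (harmonic amplitudes decay by 2^-k, total bounded, so shapes
are organic but never self-intersect). The clean class-mean image is
blurred (σ = 1 px) before Gaussian noise is added; `boundary_contrast`
sets the separation between adjacent class means in units of the noise σ,
and intensity-only classification accuracy decreases monotonically as it
drops through {4, 2, 1, 0.5} (a tested property). Defaults: 128×128
(N = 256 tokens at P = 8; a 512×512 option matches the clinical image
size, at quadratic attention cost), contrast 2.0, noise σ 0.05 — boundary
pixels are ambiguous but the task is learnable. Placement uses bounded
rejection sampling (the exact containment test is authoritative; the
proposal radius anneals downward under repeated failure) and raises an
error naming the violated constraint if a spec is infeasible. A two-channel
option emulates dual-modality input as a contrast-remapped copy of the
image with independent noise.

What phantoms do **not** capture: CT/MR physics (beam hardening, bias
fields, partial volume), anatomical shape priors, inter-slice continuity,
class imbalance at clinical severity, and annotation noise. Passing tests
on phantoms therefore demonstrates that the architecture, loss, optimiser
and metrics are implemented correctly and that the model can exploit
long-range structure — not that clinical-grade accuracy would be reached
on real data, which additionally requires GPU-scale training on the real
cohorts.

## Problem sizes

Tests and the acceptance script run deliberately small problems chosen as
the smallest sizes at which each property is meaningful: oracle checks on
≤32×32 masks and ≤8-token sequences; the overfit check trains the full
reference configuration (29.7M parameters) on eight 128² phantoms with at
most 200 Adam steps; the ablation comparison (variant 4 vs 1) uses a
narrow desk-scale configuration of the same topology — widths (8,16,24,32),
one block per stage, d=32/h=4/L=1 — on thirty 64² bilateral phantoms,
three seeds, trained with the full early-stopping protocol at a 40-epoch
cap. The bilateral archetype is used for this comparison because it is the
regime in which the ablated components carry information (class identity
is a long-range cue there); on the organ archetype at this scale the two
variants are statistically tied. The patch-size sweep checks its
bookkeeping (token counts N = HW/P², one row per admissible size) without
training.

## Known limitations

* Training is CPU-bound at roughly seconds per reference-configuration
  step at 128²; the 512² clinical scale is supported but slow.
* Early-stopping patience, ε, dropout placement, ResNet depths and
  transformer depth/width are package choices where the protocol is
  silent; all are config-exposed.
* The RVD sign convention is (|G|−|P|)/|P|: negative values mean
  over-segmentation.
* 3D context is only available through volume-mode evaluation; the network
  itself is strictly 2D slice-wise.
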