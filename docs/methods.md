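# Methods

## Scope and design intent

`pisnet` implements a compact encoder–decoder for binary segmentation of
point-of-care medical images, together with the infrastructure needed to
train and evaluate it reproducibly on one CPU: a numpy autodiff engine, a
synthetic-data generator emulating three imaging modalities, a data
pipeline for paired image/mask datasets, and a training harness. The six
ablation variants share one code path and differ only in configuration
flags, so parameter-count and behavioural comparisons between them are
meaningful.

## Architecture

### Skeleton

Five encoder stages at default widths (16, 32, 128, 160, 256). Stages 1–3
are convolutional: 3×3 conv → batch norm → 2×2 max pool → ReLU. Stages 4–5
are token-mixing stages entered through overlapping 3×3 stride-2 patch
embeds with layer normalisation. Tokenization with stride 2 is this
boundary patch embed; inside a residual mixing block the tokens are simply
the channel vectors at each spatial position, so the in-block linear
layers act per token. The decoder mirrors the encoder: 3×3 conv + BN,
bilinear ×2 upsampling (align-corners false), ReLU, additive skip from the
matching encoder stage, and token-mixing blocks on the two deepest decoder
stages (widths 160, 128).

### Diagonal-axial MLP block

Pipeline (C channels, H×W):

1. layer norm;
2. height shift: channels split into 5 contiguous groups translated
   vertically by (−2, −1, 0, +1, +2) pixels, zero-filled;
3. per-token linear C→C;
4. depthwise 3×3 convolution (implicit positional encoding), GELU;
5. two parallel diagonal shifts of the same map: up-right and up-left by
   s = ⌊window/2⌋ with zero fill, concatenated to 2C in the fixed order
   [up-right, up-left];
6. layer norm over the 2C concat, then the fusion linear 2C→C;
7. residual addition with the block input.

The adaptive window is `max(1, isqrt(H·W) // 4)` — a quarter of the
geometric-mean side, so 4 at 16×16 and 2 at 8×8; on non-square maps the
geometric mean keeps the window inside both sides. Translating the map
content is the parameter-free equivalent of re-tiling overlapping shifted
windows, which is why the dual branches add no weights beyond the 2C→C
fusion. Per-block parameter count: 3C² + 18C. The baseline tokenized-MLP
block used by variant 2 has the same skeleton with a single branch (height
shift before fc₁, width shift before fc₂, fc₂ C→C): 2C² + 14C.

Zero-fill (rather than wrap-around) shifting is used everywhere: image
content has no periodic structure, and zero fill keeps the operator's
adjoint the opposite shift, which the gradient checks exploit.

### Hybrid downsampling

The mixed branch taps the stage-3 output (128 channels, h/8): 2×2 max pool
→ 3×3 stride-2 token conv to the mixed width → layer norm → depthwise 3×3
→ GELU, landing at bottleneck resolution (h/32). Its concat with the
256-wide linear-branch bottleneck is 330 channels. Without DR-SPP
(variant 5) a 1×1 squeeze + BN + ReLU restores the 256-channel decoder
width; with DR-SPP (variant 6) the pyramid consumes the 330-channel concat
directly and its fusion convolution is the reduction — keeping the squeeze
would make the two blocks' combined size inconsistent with the published
ablation counts (see Calibration).

A `build_symmetric_hbds(c)` constructor exposes the canonical shape
algebra — linear branch c→2c→4c over two strided stages, mixed branch to
4c, concat (8c, h/4, w/4) — used by the shape contracts.

### Dynamic residual spatial pyramid pooling

At the bottleneck (C′ channels, H′×W′): three stride-1 max-pool branches
with kernels k_i = odd(i·base), base = max(1, isqrt(H′·W′) // 4), paddings
⌊k_i/2⌋ (shape preserving); each pooled map passes a 1×1 conv to the
fusion width; a 3×3 convolutional residual branch (switchable to pure
identity via `DRSPPConfig.residual_conv=False`) keeps the unpooled
features; channel concat — 4C′ when input and fusion widths agree — then a
3×3 fusion conv to the decoder width. Pooling itself contributes zero
trainable parameters, which the tests assert by enumerating the
constructed weight arrays. Stride-1 pooling with same-padding is the
standard resolution for concatenating pyramid levels of one spatial size;
pooled branches then dominate the input pointwise and are monotone in
every input value, two properties the suite checks.

## Calibration of unstated widths

The source architecture publishes per-variant parameter totals but not the
internal widths of the new blocks. The package therefore fixes the
skeleton to the open baseline's widths (16, 32, 128, 160, 256), which
reproduces the baseline's 1.47 M exactly, and calibrates the remaining
internals once, jointly, against the published ablation totals
(1.61 / 4.75 / 1.78 / 5.46 M at two decimals):

- the LN on the 2C concat in the DA-MLP block (variant 3 → 1.6076 M);
- DR-SPP internals as described above (variant 4 → 4.7546 M);
- mixed-branch width 74 with the 3×3 token conv (variant 5 → 1.7790 M);
- DR-SPP consuming the HBDS concat directly in variant 6 (→ 5.4585 M).

The mixed width 74 and the variant-6 wiring are calibration outcomes, not
published values; they are frozen as package defaults and not revisited.
The plain U-Net reference (variant 1) uses bilinear-upsampling decoder
convs and counts 34.52 M — it anchors nothing.

## Losses and metrics

- Soft Dice loss uses ε = 1e-5 smoothing in numerator and denominator, so
  empty-prediction/empty-truth scores zero loss; BCE clamps probabilities
  to [ε, 1−ε] before the logs.
- Evaluation metrics use exact ratios TP/(TP+FP+FN) and
  2TP/(FP+2TP+FN): their denominators vanish only for empty-vs-empty,
  which is defined as (1, 1) — the conservative convention for
  lesion-free patches — and exactness preserves the identity
  Dice = 2·IoU/(1+IoU) to machine precision.
- Binarisation threshold 0.5, with `>=` so a constant-0.5 map predicts
  foreground (the tie-break is asserted in a test).
- Metrics are computed per image and averaged, not pixel-pooled.

## Training recipe

Adam with β₁ = 0.9 (the "momentum" knob), β₂ = 0.999; learning rate 1e-4
cosine-annealed to 1e-5 across the configured epochs; batch size 8; 400
epochs at full scale. No early stopping; the best-validation checkpoint is
retained, and the validation split is the test split (no third split).
Splitting is a seeded permutation with train size round-half-up(0.8·n).
Non-finite loss aborts with a diagnostic rather than continuing. All
randomness (parameter init, batch order, split, synthetic data) derives
from explicit integer seeds; two runs with one seed are bit-identical.

The overfit smoke recipe — the package's convergence check — trains the
width-reduced full model (widths scaled ×0.25, 343 k parameters) for 300
steps on 16 synthetic 64×64 ultrasound-like images at lr 3e-3→3e-4. The
higher rate suits a 300-step budget on 343 k parameters; the full-scale
1e-4 recipe is far from converged in 300 steps at any width. It reaches
train Dice ≥ 0.95 in ~25 s on one CPU core with a smoothly decreasing
loss curve.

## Synthetic data

The generator emulates the statistical character of three modalities:
ultrasound (1–2 hypoechoic blobs as thresholded sums of anisotropic
Gaussians, multiplicative speckle, per-lesion extent shrinking with lesion
count), high-aspect-ratio lesions on non-square canvases (ratio drawn from
1.3–2.2, exercising anisotropic resize distortion), and nuclei fields
(30–200 rotated ellipses whose base radius co-varies with count to keep
coverage in band). Nominal foreground-fraction bands — 2–15 %, 10–40 %,
5–20 % — are asserted over 100 seeded images per preset. Masks are exact
rasterised supports; images lie in [0, 1].

What the generator does *not* emulate: physically realistic speckle
statistics (Rayleigh/Nakagami), acoustic shadowing, hair/ruler artefacts
in dermoscopy, stain variation in H&E, or ambiguous lesion boundaries.
Tests passing on these fixtures therefore demonstrate mechanical
correctness, convergence and reproducibility of the implementation — not
clinical segmentation quality, which only the real benchmarks can show.

## Numerical infrastructure

A minimal tape-based reverse-mode autodiff over numpy arrays carries the
whole model: dense/grouped 2-D convolution (im2col forward, col2im
backward), separable max pooling (two 1-D passes with argmax tracking —
O(k) work and O(HW) memory, so the adaptive pyramid can request kernels
comparable to the map side), channel layer norm, batch norm with running
statistics, bilinear resizing as a pair of interpolation matrices,
zero-fill shifts, and the elementwise/reduction primitives the losses
need. Every adjoint is validated against central finite differences in
float64. Parameters and activations are float32; losses and metrics
accumulate in float64. Initialisation is Kaiming-uniform from a globally
seeded generator. Max-pool gradient ties route to the first maximum
encountered (column-first), a fixed deterministic choice.

Checkpoints are `.npz` named-weight archives with the model config
embedded as JSON, sufficient to rebuild bit-identically; a state-dict
mismatch on load is an error, never silent.

## Desk-scale problem sizes

The test-suite and the reproduction script run on one CPU core: parameter
counts at the full default widths; forward contracts at 64–256 px; oracle
equivalences on 8×8–16×16 maps; patch-grid arithmetic on thirty
synthetic 1000×1000 tiles; and the 300-step overfit run above. Full
benchmark training (hundreds of epochs at 256–512 px on the public
datasets) is out of scope here and requires the real data.

## Known limitations

- Binary segmentation only; one output channel.
- Input sizes must be divisible by 16 (encoder stride); no tiling-based
  inference for arbitrary sizes.
- The numpy engine is single-threaded per op and orders of magnitude
  slower than a GPU framework; it is meant for desk-scale verification
  and small studies, not full benchmark training.
- Variant 1 (U-Net) is a structural reference, wider than the canonical
  transposed-conv implementation by its bilinear-upsampling decoder.
- The calibrated mixed-branch width (74) and variant-6 wiring are
  reverse-engineered from published totals and may differ from the
  original authors' unpublished choices.
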