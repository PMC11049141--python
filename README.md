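# pisnet

A lightweight MLP–CNN hybrid encoder–decoder for binary medical image
segmentation, aimed at point-of-care settings where models must be small
(a few million parameters) and fast on modest hardware. It targets the
kinds of data those devices produce — speckle-noisy breast ultrasound,
dermoscopy photographs of widely varying aspect ratio, and H&E histology
tiles dense with small nuclei — and addresses two problems that loom large
there: overly homogeneous feature extraction in tokenized-MLP stages, and
the anisotropic distortion introduced when heterogeneous native sizes are
resized to one training resolution.

The package is implemented in pure numpy/scipy, including a small
tape-based reverse-mode autodiff engine (`pisnet.autodiff`) that powers
training; no deep-learning framework is required.

## The model

The network is a five-stage U-shape: three convolutional stages
(3×3 conv + BN + 2×2 max-pool) and two token-mixing stages entered through
strided 3×3 patch embeds, with a mirrored decoder (bilinear upsampling,
additive skips). Three elements distinguish it from the tokenized-MLP
baseline:

**Diagonal-axial MLP block (DA-MLP).** For tokens X with C channels on an
H×W grid, the block computes

    X_h = fc₁(Shift_height(LN(X)))            # height shift over 5 channel groups
    X_m = GELU(DWConv₃ₓ₃(X_h))                # depthwise positional encoding
    X_d = LN([Shift_lr(X_m), Shift_rl(X_m)])  # dual diagonal shifts, concat to 2C
    X_out = X + fc₂(X_d)                      # fusion linear 2C -> C, residual

where `Shift_lr`/`Shift_rl` translate the map along the two image
diagonals by s = ⌊window/2⌋ pixels with zero fill, and the window adapts
to the map: window = max(1, ⌊⌊√(H·W)⌋/4⌋). Translating by half a window
is the parameter-free equivalent of re-tiling shifted windows with
half-window overlap, so the two branches share all trainable weights.

**Hybrid downsampling (HBDS).** In parallel with the linear token-stage
path, a mixed branch applies a 2×2 max pool (a nonlinear, parameter-free
reduction) followed by a strided token projection and depthwise encoding;
the two branches concatenate at the bottleneck, so it carries both smooth
linear features and pooled extremal ones.

**Dynamic residual spatial pyramid pooling (DR-SPP).** At the bottleneck,
three stride-1 max-pool branches with input-adaptive odd kernels
k_i = odd(i·⌊⌊√(H′·W′)⌋/4⌋) (the classic 5/9/13 pyramid at 16×16) run next
to a convolutional residual branch; the four maps concatenate to 4C′
channels and a 3×3 convolution fuses them back to the decoder width,
giving the bottleneck distortion-robust multi-scale receptive fields.

Training minimises L = λ₁·L_BCE + λ₂·L_Dice (λ₁ = 0.5, λ₂ = 1) with Adam
(lr 1e-4 cosine-annealed to 1e-5, β₁ = 0.9, batch 8). Evaluation
binarises at 0.5 and reports per-image IoU = TP/(TP+FP+FN) and
Dice = 2TP/(FP+2TP+FN), averaged over images.

Six ablation variants isolate the contributions: (1) plain U-Net,
(2) tokenized-MLP baseline, (3) DA-MLP stages, (4) +DR-SPP, (5) +HBDS,
(6) the full model. At the default configuration they count 1.47, 1.61,
4.75, 1.78 and 5.46 M trainable parameters (variants 2–6).

## Worked example

Overfit the width-reduced full model (stage widths 4/8/32/40/64, 343,509
parameters) on 16 synthetic 64×64 ultrasound-like images:

```python
from pisnet import ModelConfig, SyntheticSpec, generate_dataset
from pisnet.train import TrainConfig, train_steps
from pisnet.data import to_batch
from pisnet.model import predict
from pisnet.losses import evaluate_batch, summarize

samples = generate_dataset(SyntheticSpec(
    n_images=16, size=64, modality_preset="ultrasound_blob", seed=7))
cfg = TrainConfig(model=ModelConfig(variant_id=6, input_size=64).scaled(0.25),
                  learning_rate=3e-3, min_learning_rate=3e-4,
                  batch_size=8, epochs=1, seed=7)
model, curve = train_steps(cfg, samples, n_steps=300)

x, y = to_batch(samples, 1)
stats = summarize(evaluate_batch(predict(model, x)[:, 0], y[:, 0]))
print(f"loss: step 1 {curve[0]:.3f} -> step 300 {curve[-1]:.3f}")
print(f"train IoU {stats['mean_iou']:.4f}  train Dice {stats['mean_dice']:.4f}")
```

Output (about half a minute on one CPU core):

```
loss: step 1 1.213 -> step 300 0.055
train IoU 0.9667  train Dice 0.9830
```

The compound loss falls from 1.21 (an untrained model near the ln 2 ≈ 0.69
BCE floor plus a Dice loss near 1) to 0.06, and the model reproduces the
training masks almost exactly — the expected behaviour for a
segmentation network memorising 16 images.

The same workflow is available from the shell:

```bash
pisnet count-params --variant 6     # variant 6: 5,458,465 trainable parameters (5.46 M)
pisnet synth --preset nuclei_field --n 16 --seed 1 --out data/synth
pisnet train --config cfg.yaml --out runs/demo
pisnet eval --ckpt runs/demo/checkpoint.npz --data data/synth --out runs/eval
```

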