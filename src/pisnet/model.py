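"""Encoder-decoder assembly, ablation variants and checkpointing.

The network is a five-stage U-shaped hybrid: three convolutional stages
(3x3 conv + BN + 2x2 max pool) followed by two token-mixing stages entered
through strided 3x3 patch embeds.  The decoder mirrors the encoder with
bilinear upsampling, additive skip connections, and token-mixing blocks on
the two deepest decoder stages.  Six ablation variants isolate each design
element:

  1  plain U-Net (64 channels in the first stage)
  2  baseline: axial tokenized-MLP blocks in stages 4-5
  3  diagonal-axial MLP blocks in stages 4-5
  4  variant 3 + DR-SPP at the bottleneck
  5  variant 3 + hybrid downsampling (mixed pooled branch into the bottleneck)
  6  variant 3 + DR-SPP + hybrid downsampling (the full model)

With both DR-SPP and the hybrid downsampler enabled, the pyramid consumes
the two-branch concat directly — its fusion convolution is the channel
reduction back to the decoder width.  With the downsampler alone, a 1x1
squeeze restores the decoder width.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .autodiff import Tensor, concat, no_grad
from .drspp import DRSPP, DRSPPConfig
from .hbds import MixedDownsampleBranch
from .tensor_blocks import DAMLPBlock, TokMLPBlock, TokenProjection

DEFAULT_STAGE_WIDTHS = (16, 32, 128, 160, 256)
DEFAULT_MIXED_WIDTH = 74

_VARIANTS = {
    1: dict(kind="unet", use_hbds=False, use_drspp=False),
    2: dict(kind="tok", use_hbds=False, use_drspp=False),
    3: dict(kind="da", use_hbds=False, use_drspp=False),
    4: dict(kind="da", use_hbds=False, use_drspp=True),
    5: dict(kind="da", use_hbds=True, use_drspp=False),
    6: dict(kind="da", use_hbds=True, use_drspp=True),
}


@dataclass(frozen=True)
class ModelConfig:
    variant_id: int = 6
    stage_widths: tuple = DEFAULT_STAGE_WIDTHS
    mixed_width: int = DEFAULT_MIXED_WIDTH
    input_size: int = 256
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if self.variant_id not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant_id}; expected 1-6")
        if len(self.stage_widths) != 5:
            raise ValueError("stage_widths must have 5 entries")
        if any(a >= b for a, b in zip(self.stage_widths, self.stage_widths[1:])):
            raise ValueError("stage_widths must be strictly increasing")
        if self.input_size % 16:
            raise ValueError("input_size must be divisible by 16")
        if self.in_channels not in (1, 3):
            raise ValueError("in_channels must be 1 (grayscale) or 3 (RGB)")
        if self.out_channels != 1:
            raise ValueError("binary task: out_channels must be 1")

    @property
    def block_kind(self):
        return _VARIANTS[self.variant_id]["kind"]

    @property
    def use_hbds(self):
        return _VARIANTS[self.variant_id]["use_hbds"]

    @property
    def use_drspp(self):
        return _VARIANTS[self.variant_id]["use_drspp"]

    @property
    def stage_kinds(self):
        if self.block_kind == "unet":
            return ("conv",) * 5
        return ("conv", "conv", "conv", "mlp", "mlp")

    def scaled(self, factor):
        """Width-reduced copy (all stage widths and the mixed width scaled)."""
        widths = tuple(max(4, round(w * factor)) for w in self.stage_widths)
        return ModelConfig(self.variant_id, widths,
                           max(2, round(self.mixed_width * factor)),
                           self.input_size, self.in_channels, self.out_channels)

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["stage_widths"] = tuple(d["stage_widths"])
        return cls(**d)


class _ConvStage(nn.Module):
    """3x3 conv + BN, pooled and rectified by the caller."""

    def __init__(self, cin, cout):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, padding=1)
        self.bn = nn.BatchNorm2d(cout)
        self.pool = nn.MaxPool2d(2)

    def forward(self, x):
        return self.pool(self.bn(self.conv(x))).relu()


class PISNet(nn.Module):
    """The hybrid MLP-CNN segmentation network (ablation variants 2-6)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        if cfg.block_kind == "unet":
            raise ValueError("variant 1 is built by the UNet class")
        self.cfg = cfg
        w1, w2, w3, w4, w5 = cfg.stage_widths
        Block = DAMLPBlock if cfg.block_kind == "da" else TokMLPBlock

        self.enc1 = _ConvStage(cfg.in_channels, w1)
        self.enc2 = _ConvStage(w1, w2)
        self.enc3 = _ConvStage(w2, w3)
        self.patch_embed3 = TokenProjection(w3, w4, stride=2)
        self.block1 = Block(w4)
        self.norm3 = nn.LayerNorm(w4)
        self.patch_embed4 = TokenProjection(w4, w5, stride=2)
        self.block2 = Block(w5)
        self.norm4 = nn.LayerNorm(w5)

        bottleneck = w5
        if cfg.use_hbds:
            self.mixed = MixedDownsampleBranch(w3, cfg.mixed_width)
            bottleneck = w5 + cfg.mixed_width
            if not cfg.use_drspp:
                # restore the decoder width with a 1x1 squeeze
                self.squeeze = nn.ChannelLinear(bottleneck, w5)
                self.squeeze_bn = nn.BatchNorm2d(w5)
                bottleneck = w5
        if cfg.use_drspp:
            self.drspp = DRSPP(DRSPPConfig(bottleneck, w5))
            bottleneck = w5

        self.decoder1 = nn.Conv2d(bottleneck, w4, 3, padding=1)
        self.dbn1 = nn.BatchNorm2d(w4)
        self.dblock1 = Block(w4)
        self.dnorm3 = nn.LayerNorm(w4)
        self.decoder2 = nn.Conv2d(w4, w3, 3, padding=1)
        self.dbn2 = nn.BatchNorm2d(w3)
        self.dblock2 = Block(w3)
        self.dnorm4 = nn.LayerNorm(w3)
        self.decoder3 = nn.Conv2d(w3, w2, 3, padding=1)
        self.dbn3 = nn.BatchNorm2d(w2)
        self.decoder4 = nn.Conv2d(w2, w1, 3, padding=1)
        self.dbn4 = nn.BatchNorm2d(w1)
        self.decoder5 = nn.Conv2d(w1, w1, 3, padding=1)
        self.final = nn.ChannelLinear(w1, cfg.out_channels)

    @staticmethod
    def _up(x):
        return x.bilinear_resize(2 * x.shape[2], 2 * x.shape[3])

    def forward(self, x):
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, "
                f"got {x.shape[1]}")
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("spatial size must be divisible by 16")
        t1 = self.enc1(x)
        t2 = self.enc2(t1)
        t3 = self.enc3(t2)
        t4 = self.norm3(self.block1(self.patch_embed3(t3)))
        out = self.norm4(self.block2(self.patch_embed4(t4)))

        if self.cfg.use_hbds:
            out = concat([out, self.mixed(t3)], axis=1)
            if not self.cfg.use_drspp:
                out = self.squeeze_bn(self.squeeze(out)).relu()
        if self.cfg.use_drspp:
            out = self.drspp(out)

        out = self._up(self.dbn1(self.decoder1(out))).relu() + t4
        out = self.dnorm3(self.dblock1(out))
        out = self._up(self.dbn2(self.decoder2(out))).relu() + t3
        out = self.dnorm4(self.dblock2(out))
        out = self._up(self.dbn3(self.decoder3(out))).relu() + t2
        out = self._up(self.dbn4(self.decoder4(out))).relu() + t1
        out = self._up(self.decoder5(out)).relu()
        return self.final(out)


class _DoubleConv(nn.Module):
    def __init__(self, cin, cout):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, padding=1)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1)
        self.bn2 = nn.BatchNorm2d(cout)

    def forward(self, x):
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class UNet(nn.Module):
    """Plain U-Net reference (variant 1), 64 channels in the first stage.

    Bilinear upsampling followed by a 3x3 halving convolution on each
    decoder stage; skip connections by channel concatenation.
    """

    def __init__(self, cfg: ModelConfig, base=64):
        super().__init__()
        self.cfg = cfg
        c = [base, base * 2, base * 4, base * 8, base * 16]
        self.enc1 = _DoubleConv(cfg.in_channels, c[0])
        self.enc2 = _DoubleConv(c[0], c[1])
        self.enc3 = _DoubleConv(c[1], c[2])
        self.enc4 = _DoubleConv(c[2], c[3])
        self.bottom = _DoubleConv(c[3], c[4])
        self.pool = nn.MaxPool2d(2)
        self.up4 = nn.Conv2d(c[4], c[3], 3, padding=1)
        self.dec4 = _DoubleConv(c[4], c[3])
        self.up3 = nn.Conv2d(c[3], c[2], 3, padding=1)
        self.dec3 = _DoubleConv(c[3], c[2])
        self.up2 = nn.Conv2d(c[2], c[1], 3, padding=1)
        self.dec2 = _DoubleConv(c[2], c[1])
        self.up1 = nn.Conv2d(c[1], c[0], 3, padding=1)
        self.dec1 = _DoubleConv(c[1], c[0])
        self.final = nn.ChannelLinear(c[0], cfg.out_channels)

    def forward(self, x):
        e1 = self.enc1(x)
        e2 = self.enc2(self.pool(e1))
        e3 = self.enc3(self.pool(e2))
        e4 = self.enc4(self.pool(e3))
        b = self.bottom(self.pool(e4))

        def up(t, conv, skip, dec):
            t = conv(t.bilinear_resize(2 * t.shape[2], 2 * t.shape[3]))
            return dec(concat([skip, t], axis=1))

        d = up(b, self.up4, e4, self.dec4)
        d = up(d, self.up3, e3, self.dec3)
        d = up(d, self.up2, e2, self.dec2)
        d = up(d, self.up1, e1, self.dec1)
        return self.final(d)


def build_model(cfg: ModelConfig):
    """Construct the segmentation model for the configured ablation variant."""
    if cfg.block_kind == "unet":
        return UNet(cfg)
    return PISNet(cfg)


def count_trainable_parameters(model):
    """Exact element count over every trainable weight array."""
    return int(sum(p.data.size for p in model.parameters()))


def predict(model, images):
    """Per-pixel foreground probabilities for a batch, in evaluation mode.

    Returns an (n, 1, H, W) float array with values strictly inside (0, 1)
    (sigmoid outputs are clamped away from the exactly-saturated floats).
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4:
        raise ValueError("expected a batch shaped (n, c, h, w)")
    was_training = model.training
    model.eval()
    try:
        with no_grad():
            logits = model(Tensor(images))
        probs = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
    finally:
        model.train(was_training)
    return np.clip(probs, 1e-7, 1 - 1e-7)


def save_checkpoint(path, model, extra=None):
    """Named-weight archive with the model config embedded alongside."""
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path):
    """Rebuild a model bit-identically from a checkpoint archive."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    cfg = ModelConfig.from_dict(meta["config"])
    model = build_model(cfg)
    model.load_state_dict(state)
    return model, cfg, meta.get("extra", {})
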