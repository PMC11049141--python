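"""Diagonal-axial token-mixing blocks and their constituent operators.

The diagonal-axial MLP (DA-MLP) block mixes tokens along the height axis and
along both image diagonals.  Its pipeline is

    x -> LN -> height shift (channel groups) -> linear -> depthwise conv
      -> GELU -> {shift up-right, shift up-left} -> concat (2C) -> LN
      -> linear (2C -> C) -> + x

The two diagonal branches realise a pair of shifted windows sliding from the
bottom-left and bottom-right corners toward the top; translating the feature
content by half a window is the parameter-free equivalent of re-tiling with
half-window overlap, so the branches share all trainable weights and add
none of their own.

Functional operators in this module act on single (C, H, W) numpy feature
maps — the form the contracts and oracles are written against.  The
``*Block`` classes are the batched autodiff modules the models are built
from.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, _shift2d, concat

DEFAULT_HEIGHT_OFFSETS = (-2, -1, 0, 1, 2)


def validate_feature_map(x):
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"feature map must be (C, H, W), got shape {x.shape}")
    if min(x.shape) < 1:
        raise ValueError("feature map dimensions must be positive")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    return x


@dataclass(frozen=True)
class ShiftSpec:
    """Adaptive shifted-window geometry for an (H, W) feature map."""
    window_size: int
    pad: int

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.pad != self.window_size // 2:
            raise ValueError("pad must equal floor(window_size / 2)")

    @property
    def shift(self):
        """Translation distance: half the window size."""
        return self.window_size // 2


@dataclass(frozen=True)
class DAMLPConfig:
    in_channels: int
    out_channels: int
    token_embed_dim: int = 0          # 0: equal to out_channels
    dwconv_kernel: int = 3
    height_shift_offsets: tuple = DEFAULT_HEIGHT_OFFSETS
    stride: int = 1

    def __post_init__(self):
        ratio = self.out_channels / self.in_channels
        if ratio not in (1.0, 2.0, 4.0):
            raise ValueError("out/in channel ratio must be 1, 2 or 4")
        if self.dwconv_kernel % 2 == 0:
            raise ValueError("dwconv kernel must be odd")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")

    @property
    def embed_dim(self):
        return self.token_embed_dim or self.out_channels


def compute_shift_geometry(height, width):
    """Window size and padding adapted to the map's geometric-mean side.

    window = max(1, floor(floor(sqrt(H*W)) / 4)); pad = floor(window / 2).
    A 16x16 map gets window 4 (a quarter of the side), an 8x8 map window 2.
    """
    if height < 1 or width < 1:
        raise ValueError("dimensions must be positive")
    window = max(1, math.isqrt(height * width) // 4)
    return ShiftSpec(window_size=window, pad=window // 2)


def shift_height(x, offsets):
    """Translate contiguous channel groups vertically with zero fill.

    Group g of channels moves by offsets[g] rows (positive = down); shape is
    preserved and vacated rows are zero.
    """
    x = validate_feature_map(x)
    c, h, _ = x.shape
    for off in offsets:
        if abs(off) >= h:
            raise ValueError(f"|offset| {abs(off)} must be < height {h}")
    if c < len(offsets):
        raise ValueError("more offset groups than channels")
    out = Tensor(x[None]).shift_rows_grouped(tuple(offsets))
    return out.data[0]


def diagonal_shift(x, spec, direction):
    """Translate a feature map along an image diagonal with zero fill.

    direction 'lr': the window slides from the bottom-left corner toward the
    top-right, moving content up and right by s = floor(window/2) pixels.
    direction 'rl': bottom-right toward top-left, content moves up and left.
    """
    x = validate_feature_map(x)
    if direction not in ("lr", "rl"):
        raise ValueError(f"unknown direction {direction!r}")
    if spec.window_size >= min(x.shape[1], x.shape[2]):
        raise ValueError("window does not fit inside the map")
    s = spec.shift
    dcol = s if direction == "lr" else -s
    return _shift2d(x, -s, dcol)


def token_project(x, embed_dim, stride=1, module=None):
    """Project a feature map into a token map of `embed_dim` channels.

    A 3x3 overlapping convolution; stride 2 also halves the spatial size
    (the downsampling patch embed between stages).  Pass `module` to reuse
    trained weights; otherwise a freshly initialised projection is applied.
    """
    x = validate_feature_map(x)
    if embed_dim < 1:
        raise ValueError("embed_dim must be >= 1")
    if stride not in (1, 2):
        raise ValueError("stride must be 1 or 2")
    if x.shape[1] % stride or x.shape[2] % stride:
        raise ValueError("spatial size must be divisible by stride")
    if module is None:
        module = TokenProjection(x.shape[0], embed_dim, stride=stride)
    return module(Tensor(x[None].astype(np.float32))).data[0]


def dwconv_encode(x, module=None):
    """Depthwise 3x3 convolution: per-channel positional encoding."""
    x = validate_feature_map(x)
    if module is None:
        module = nn.DepthwiseConv2d(x.shape[0])
    return module(Tensor(x[None].astype(np.float32))).data[0]


class TokenProjection(nn.Module):
    """Overlapping 3x3 convolutional patch embed (the Tok operator)."""

    def __init__(self, in_channels, embed_dim, stride=1, norm=True):
        super().__init__()
        self.proj = nn.Conv2d(in_channels, embed_dim, 3, stride=stride, padding=1)
        self.norm = nn.LayerNorm(embed_dim) if norm else None

    def forward(self, x):
        x = self.proj(x)
        if self.norm is not None:
            x = self.norm(x)
        return x


class DAMLPBlock(nn.Module):
    """Residual diagonal-axial MLP mixing block (shape preserving).

    Parameters per block: 3C^2 + 18C (fc1 C->C, fc2 2C->C, depthwise 3x3,
    two layer norms).  The dual diagonal branches reuse the shared layers
    and contribute no weights of their own.
    """

    def __init__(self, dim, height_offsets=DEFAULT_HEIGHT_OFFSETS,
                 dwconv_kernel=3):
        super().__init__()
        self.height_offsets = tuple(height_offsets)
        self.norm1 = nn.LayerNorm(dim)
        self.fc1 = nn.ChannelLinear(dim, dim)
        self.dwconv = nn.DepthwiseConv2d(dim, dwconv_kernel)
        self.norm2 = nn.LayerNorm(2 * dim)
        self.fc2 = nn.ChannelLinear(2 * dim, dim)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        s = compute_shift_geometry(h, w).shift
        t = self.norm1(x)
        t = t.shift_rows_grouped(self.height_offsets)
        t = self.fc1(t)
        t = self.dwconv(t)
        t = t.gelu()
        lr = t.shift2d(-s, s)     # bottom-left -> top-right
        rl = t.shift2d(-s, -s)    # bottom-right -> top-left
        d = concat([lr, rl], axis=1)
        d = self.norm2(d)
        return x + self.fc2(d)


class TokMLPBlock(nn.Module):
    """Axial tokenized-MLP mixing block (the re-implemented baseline).

    Same skeleton as the DA-MLP block but with a single branch: a height
    shift before fc1 and a width shift before fc2, fc2 mapping C -> C.
    """

    def __init__(self, dim, offsets=DEFAULT_HEIGHT_OFFSETS):
        super().__init__()
        self.offsets = tuple(offsets)
        self.norm1 = nn.LayerNorm(dim)
        self.fc1 = nn.ChannelLinear(dim, dim)
        self.dwconv = nn.DepthwiseConv2d(dim, 3)
        self.fc2 = nn.ChannelLinear(dim, dim)

    def forward(self, x):
        t = self.norm1(x)
        t = t.shift_rows_grouped(self.offsets)
        t = self.fc1(t)
        t = self.dwconv(t)
        t = t.gelu()
        t = t.shift_cols_grouped(self.offsets)
        return x + self.fc2(t)


def da_mlp_forward(x, block=None, cfg: DAMLPConfig | None = None):
    """Run one diagonal-axial MLP block over a (C, H, W) feature map.

    Either an existing :class:`DAMLPBlock` or a :class:`DAMLPConfig` (from
    which a fresh block is built; in_channels must equal out_channels for
    the residual form) may be given.
    """
    x = validate_feature_map(x)
    if block is None:
        cfg = cfg or DAMLPConfig(x.shape[0], x.shape[0])
        if cfg.in_channels != cfg.out_channels:
            raise ValueError("residual block requires in_channels == out_channels")
        block = DAMLPBlock(cfg.in_channels,
                           height_offsets=cfg.height_shift_offsets,
                           dwconv_kernel=cfg.dwconv_kernel)
    if x.shape[0] != block.fc1.weight.shape[1]:
        raise ValueError("channel count does not match block width")
    return block(Tensor(x[None].astype(np.float32))).data[0]
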