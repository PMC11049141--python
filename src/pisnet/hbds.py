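"""Hybrid downsampling: parallel linear and nonlinear reduction branches.

Over the token stages of the encoder, the purely linear downsampling path
(stacked token-mixing blocks with strided patch embeds) is complemented by a
mixed branch that first discards non-maximal activations (2x2 max pooling —
a nonlinear, parameter-free reduction) and then applies a light tokenized
projection with a depthwise positional encoding.  The two branches meet at
the bottleneck resolution and are fused by channel concatenation, so the
bottleneck carries both the smooth linear features and the pooled extremal
ones.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, concat
from .tensor_blocks import validate_feature_map


@dataclass(frozen=True)
class HBDSConfig:
    in_channels: int            # width entering the token stages
    linear_channels: int        # width of the linear-branch bottleneck
    mixed_channels: int = 74    # width of the mixed (pooled) branch
    dwconv_kernel: int = 3

    def __post_init__(self):
        if min(self.in_channels, self.linear_channels, self.mixed_channels) < 1:
            raise ValueError("channel counts must be positive")

    @property
    def out_channels(self):
        """Concatenated width handed on after fusion."""
        return self.linear_channels + self.mixed_channels


def max_pool_halve(x):
    """2x2 max pooling on a (C, H, W) map; H and W must be even."""
    x = validate_feature_map(x)
    c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("spatial dimensions must be even")
    return x.reshape(c, h // 2, 2, w // 2, 2).max(axis=(2, 4))


class MixedDownsampleBranch(nn.Module):
    """maxpool(2) -> 3x3 stride-2 token conv -> LN -> DWConv -> GELU.

    Maps (c, h, w) to (mixed_channels, h/4, w/4): the pooling contributes
    the nonlinear quarter-resolution reduction, the strided token
    projection the remaining halving plus the channel change.
    """

    def __init__(self, in_channels, mixed_channels, dwconv_kernel=3):
        super().__init__()
        self.pool = nn.MaxPool2d(2)
        self.token = nn.Conv2d(in_channels, mixed_channels, 3,
                               stride=2, padding=1)
        self.norm = nn.LayerNorm(mixed_channels)
        self.dwconv = nn.DepthwiseConv2d(mixed_channels, dwconv_kernel)

    def forward(self, x):
        t = self.pool(x)
        t = self.norm(self.token(t))
        return self.dwconv(t).gelu()


class HBDS(nn.Module):
    """Fuse a linear downsampling path with the mixed pooled branch.

    `linear_path` is a callable mapping the stage input to the linear
    bottleneck features (in the full model: patch embed -> block -> patch
    embed -> block); the mixed branch runs in parallel from the same input.
    The output is the channel concatenation [linear, mixed].
    """

    def __init__(self, cfg: HBDSConfig, linear_path):
        super().__init__()
        self.cfg = cfg
        self.linear_path = linear_path
        self.mixed = MixedDownsampleBranch(cfg.in_channels, cfg.mixed_channels,
                                           cfg.dwconv_kernel)

    def forward(self, x):
        f_linear = self.linear_path(x)
        f_mixed = self.mixed(x)
        if f_linear.shape[2:] != f_mixed.shape[2:]:
            raise ValueError(
                f"branch spatial mismatch: linear {f_linear.shape} vs "
                f"mixed {f_mixed.shape}")
        return concat([f_linear, f_mixed], axis=1)


def build_symmetric_hbds(c, h=None, w=None):
    """Canonical hybrid downsampler: (c, h, w) -> (8c, h/4, w/4).

    Linear branch: two stride-2 token-mixing stages doubling the width each
    time (c -> 2c -> 4c).  Mixed branch: pooled reduction to 4c.  The
    concatenation is 8c channels at quarter resolution.
    """
    from .tensor_blocks import DAMLPBlock, TokenProjection

    class _Linear(nn.Module):
        def __init__(self):
            super().__init__()
            self.embed1 = TokenProjection(c, 2 * c, stride=2)
            self.block1 = DAMLPBlock(2 * c)
            self.embed2 = TokenProjection(2 * c, 4 * c, stride=2)
            self.block2 = DAMLPBlock(4 * c)

        def forward(self, x):
            return self.block2(self.embed2(self.block1(self.embed1(x))))

    cfg = HBDSConfig(in_channels=c, linear_channels=4 * c, mixed_channels=4 * c)
    return HBDS(cfg, _Linear())


def hbds_forward(f, hbds: HBDS):
    """Run a hybrid-downsampling module over a (C, H, W) feature map."""
    f = validate_feature_map(f)
    if f.shape[0] != hbds.cfg.in_channels:
        raise ValueError("channel count does not match config")
    if f.shape[1] % 4 or f.shape[2] % 4:
        raise ValueError("spatial dimensions must be divisible by 4")
    return hbds(Tensor(f[None].astype(np.float32))).data[0]
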