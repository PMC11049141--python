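"""Dynamic residual spatial pyramid pooling for the encoder bottleneck.

Heterogeneous native image sizes are all resized to one training
resolution, which distorts lesions anisotropically.  To make the bottleneck
representation robust to that distortion, three parallel stride-1 max-pool
branches give it receptive fields that adapt to the bottleneck's own
spatial size: the kernel of level i is i times a quarter of the
geometric-mean side, rounded up to odd so same-padding preserves the
spatial dimensions (a 16x16 bottleneck yields the classic 5/9/13 pyramid).
A convolutional residual branch keeps the unpooled features; the four maps
are channel-concatenated and fused by a 3x3 convolution.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, concat
from .tensor_blocks import validate_feature_map


@dataclass(frozen=True)
class DRSPPConfig:
    in_channels: int
    fusion_out_channels: int
    residual_conv: bool = True   # False: pure identity residual path

    def __post_init__(self):
        if self.in_channels < 1 or self.fusion_out_channels < 1:
            raise ValueError("channel counts must be positive")


def drspp_kernels(h_prime, w_prime):
    """Input-adaptive pyramid kernels and their same-paddings.

    base = max(1, floor(floor(sqrt(H'*W')) / 4)); k_i = odd(i * base) for
    i in 1..3 (odd(k) = k + 1 if k is even).  Paddings p_i = k_i // 2 keep
    stride-1 pooling shape preserving.
    """
    if h_prime < 1 or w_prime < 1:
        raise ValueError("dimensions must be positive")
    base = max(1, math.isqrt(h_prime * w_prime) // 4)
    kernels = tuple(i * base + (1 if (i * base) % 2 == 0 else 0)
                    for i in (1, 2, 3))
    paddings = tuple(k // 2 for k in kernels)
    return kernels, paddings


class DRSPP(nn.Module):
    """Three adaptive pooled branches + convolutional residual + fusion.

    Each pooled branch is a stride-1 max pool followed by a 1x1 conv to the
    fusion width; the residual branch is a 3x3 conv at the input width.
    The concat (3*out + in channels; 4C' at the plain bottleneck where
    in == out) is fused by a 3x3 conv back to the fusion width.
    """

    def __init__(self, cfg: DRSPPConfig):
        super().__init__()
        self.cfg = cfg
        cin, cout = cfg.in_channels, cfg.fusion_out_channels
        self.branch_proj = nn.ModuleList(
            [nn.ChannelLinear(cin, cout) for _ in range(3)])
        if cfg.residual_conv:
            self.residual = nn.Conv2d(cin, cin, 3, padding=1)
        else:
            self.residual = None
            if cin != cout:
                raise ValueError("identity residual requires in == out")
        concat_width = 3 * cout + cin
        self.fusion = nn.Conv2d(concat_width, cout, 3, padding=1)

    def pooled_branches(self, x):
        """The three stride-1 pooled maps, before projection (C_in each)."""
        kernels, paddings = drspp_kernels(x.shape[2], x.shape[3])
        return [x.maxpool2d(k, stride=1, padding=p)
                for k, p in zip(kernels, paddings)]

    def forward(self, x):
        pooled = [proj(b) for proj, b in
                  zip(self.branch_proj, self.pooled_branches(x))]
        res = self.residual(x) if self.residual is not None else x
        return self.fusion(concat(pooled + [res], axis=1))


def drspp_forward(f, block: DRSPP | None = None):
    """Run DR-SPP over a (C', H', W') feature map; shape -> (out, H', W')."""
    f = validate_feature_map(f)
    if block is None:
        block = DRSPP(DRSPPConfig(f.shape[0], f.shape[0]))
    if f.shape[0] != block.cfg.in_channels:
        raise ValueError("channel count does not match config")
    return block(Tensor(f[None].astype(np.float32))).data[0]
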