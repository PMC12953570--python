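"""Morphological Edge Network (MEN) backbone blocks.

The MEN block is a CSP-style stage whose processed branch runs dual-path
units (DPM) built from multi-scale fusion units (MSF) and an explicit
edge enhancer.  The edge enhancer computes an edge map as the difference
between a feature and its local average, gates it through a learned 1x1
transform and a logistic, and adds the gated response back:

    E(x) = x + x * sigma(H(x - P_avg(x)))

For nonnegative input this is elementwise bounded in [x, 2x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import autograd.numpy as anp
import numpy as np
from autograd.tracer import getval

from . import nn
from .nn import functional as F


def check_feature_map(x) -> Tuple[int, int, int, int]:
    """Validate the (B, C, H, W) feature-map contract; returns the shape."""
    v = getval(x)
    if np.ndim(v) != 4:
        raise ValueError(f"feature map must be rank-4 (B,C,H,W), got rank {np.ndim(v)}")
    if any(s < 1 for s in v.shape):
        raise ValueError(f"feature map dims must be >= 1, got {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("feature map contains non-finite entries")
    return v.shape


@dataclass(frozen=True)
class ScaleSet:
    """Strictly increasing pooling grid sizes for the MSF branches."""

    scales: Tuple[int, ...] = (3, 6, 9, 12)

    def __post_init__(self):
        s = tuple(int(v) for v in self.scales)
        if not s or any(v < 1 for v in s) or any(a >= b for a, b in zip(s, s[1:])):
            raise ValueError(f"scales must be strictly increasing positive ints, got {s}")
        object.__setattr__(self, "scales", s)

    def __iter__(self):
        return iter(self.scales)

    def __len__(self):
        return len(self.scales)


@dataclass(frozen=True)
class MENConfig:
    in_channels: int
    out_channels: int
    n_units: int = 1
    scale_set: ScaleSet = field(default_factory=ScaleSet)
    hidden_channels: int = 0  # 0 -> out_channels

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1 or self.n_units < 0:
            raise ValueError("channel counts must be positive and n_units >= 0")
        h = self.hidden_channels or self.out_channels
        if h % 2:
            raise ValueError(f"hidden width {h} must be even to split into two halves")
        object.__setattr__(self, "hidden_channels", h)


class EdgeEnhancer(nn.Module):
    """x + x * sigma(H(x - avg_pool(x))) with a 3x3 replicate-padded
    average pool and H = 1x1 conv + BN."""

    def __init__(self, channels: int, pool_k: int = 3):
        super().__init__()
        self.pool_k = pool_k
        self.h = nn.Conv2d(channels, channels, 1)
        self.bn = nn.BatchNorm2d(channels)

    def forward(self, x, p):
        B, C, H, W = check_feature_map(x)
        if H < self.pool_k or W < self.pool_k:
            raise ValueError(
                f"spatial dims {(H, W)} smaller than pooling window {self.pool_k}"
            )
        local = F.avg_pool2d(x, self.pool_k, stride=1, padding=self.pool_k // 2,
                             pad_mode="edge")
        edge = x - local
        gate = F.sigmoid(self.bn(self.h(edge, p["h"]), p["bn"]))
        return x + x * gate


class MSF(nn.Module):
    """Multi-scale fusion: a local 3x3 branch plus one branch per scale
    (adaptive pool to s x s -> 1x1 transform -> bilinear upsample ->
    edge enhance), concatenated and fused by a 1x1 conv."""

    def __init__(self, channels: int, scale_set: ScaleSet = ScaleSet()):
        super().__init__()
        self.scale_set = scale_set
        self.local = nn.ConvBNAct(channels, channels, 3)
        for i, _ in enumerate(scale_set):
            setattr(self, f"t{i}", nn.ConvBNAct(channels, channels, 1))
            setattr(self, f"e{i}", EdgeEnhancer(channels))
        self.fuse = nn.ConvBNAct(channels * (len(scale_set) + 1), channels, 1)

    def forward(self, x, p):
        B, C, H, W = check_feature_map(x)
        smax = max(self.scale_set)
        if min(H, W) < smax:
            raise ValueError(f"scale {smax} exceeds spatial extent {(H, W)}")
        branches = [self.local(x, p["local"])]
        for i, s in enumerate(self.scale_set):
            y = F.adaptive_avg_pool2d(x, s)
            y = getattr(self, f"t{i}")(y, p[f"t{i}"])
            y = F.interpolate(y, (H, W), mode="bilinear")
            y = getattr(self, f"e{i}")(y, p[f"e{i}"])
            branches.append(y)
        return self.fuse(anp.concatenate(branches, axis=1), p["fuse"])


class DPM(nn.Module):
    """Dual-path unit: Z = G(concat[E(P(x)), Q(x)]) with P, Q parallel 1x1
    paths, E a serial chain of MSF units, G a fusing 1x1 conv."""

    def __init__(self, channels: int, n_msf: int = 1, scale_set: ScaleSet = ScaleSet()):
        super().__init__()
        half = max(channels // 2, 1)
        self.p = nn.ConvBNAct(channels, half, 1)
        self.q = nn.ConvBNAct(channels, half, 1)
        self.chain = nn.Sequential(*[MSF(half, scale_set) for _ in range(n_msf)])
        self.g = nn.ConvBNAct(2 * half, channels, 1)

    def forward(self, x, p):
        check_feature_map(x)
        a = self.chain(self.p(x, p["p"]), p["chain"])
        b = self.q(x, p["q"])
        return self.g(anp.concatenate([a, b], axis=1), p["g"])


class MENBlock(nn.Module):
    """CSP stage: entry 1x1 conv, channel split into (X1, X2), a serial
    chain of n DPM units on X2, concat of all intermediate states, 1x1
    fusion to the output width."""

    def __init__(self, cfg: MENConfig):
        super().__init__()
        self.cfg = cfg
        h = cfg.hidden_channels
        self.entry = nn.ConvBNAct(cfg.in_channels, h, 1)
        for i in range(cfg.n_units):
            setattr(self, f"u{i}", DPM(h // 2, scale_set=cfg.scale_set))
        self.fusion = nn.ConvBNAct((2 + cfg.n_units) * (h // 2), cfg.out_channels, 1)

    def forward(self, x, p):
        B, C, H, W = check_feature_map(x)
        if C != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, got {C}")
        h = self.entry(x, p["entry"])
        half = self.cfg.hidden_channels // 2
        x1, x2 = h[:, :half], h[:, half:]
        parts = [x1, x2]
        y = x2
        for i in range(self.cfg.n_units):
            y = getattr(self, f"u{i}")(y, p[f"u{i}"])
            parts.append(y)
        return self.fusion(anp.concatenate(parts, axis=1), p["fusion"])


# functional entry points mirroring the block surface -----------------------

def edge_enhance(x, module: EdgeEnhancer):
    return module(x)


def msf_forward(x, module: MSF):
    return module(x)


def dpm_forward(x, module: DPM):
    return module(x)


def men_block(x, cfg: MENConfig):
    return MENBlock(cfg)(x)
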