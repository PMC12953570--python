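"""Spatial-Channel Augmented Upsampling (SCAU).

A 2x upsampler that follows nearest-neighbour interpolation with a
depthwise-separable convolution, a grouped channel shuffle, a
multi-directional circular feature shift (MDFS), and a pointwise fusion
conv.  The shuffle and the shift are pure index permutations: they
conserve the multiset of activation values exactly and cost no
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from . import nn
from .men import check_feature_map


@dataclass(frozen=True)
class ShiftSpec:
    """Circular shift magnitude; quarters move (+s, -s) along height and
    (+s, -s) along width, positive meaning downward/rightward."""

    s: int = 1

    def __post_init__(self):
        if self.s < 1:
            raise ValueError("shift magnitude must be >= 1")

    def inverse(self) -> "ShiftSpec":
        return ShiftSpec(self.s)  # applied with negated signs, see mdfs


@dataclass(frozen=True)
class ShuffleSpec:
    groups: int = 4

    def __post_init__(self):
        if self.groups < 1:
            raise ValueError("groups must be >= 1")


def channel_shuffle(x, g: int):
    """Group-transpose channel permutation: channel i moves to
    (i mod g) * (C // g) + i // g.  Values are untouched."""
    B, C, H, W = check_feature_map(x)
    if C % g:
        raise ValueError(f"channels {C} not divisible by groups {g}")
    y = anp.reshape(x, (B, g, C // g, H, W))
    y = anp.transpose(y, (0, 2, 1, 3, 4))
    return anp.reshape(y, (B, C, H, W))


def _roll(x, shift: int, axis: int):
    n = x.shape[axis]
    shift %= n
    if shift == 0:
        return x
    idx_lo = [slice(None)] * x.ndim
    idx_hi = [slice(None)] * x.ndim
    idx_lo[axis] = slice(n - shift, n)
    idx_hi[axis] = slice(0, n - shift)
    return anp.concatenate([x[tuple(idx_lo)], x[tuple(idx_hi)]], axis=axis)


def mdfs(x, spec: ShiftSpec, invert: bool = False):
    """Multi-directional feature shift: split channels into four equal
    quarters, circularly shift them (+s, -s) along height and (+s, -s)
    along width respectively, and re-concatenate.  ``invert=True``
    negates every shift, exactly undoing a prior application."""
    B, C, H, W = check_feature_map(x)
    if C % 4:
        raise ValueError(f"channels {C} must be divisible by 4")
    s = spec.s
    if s >= min(H, W):
        raise ValueError(f"shift {s} must be < min spatial extent {min(H, W)}")
    if invert:
        s = -s
    q = C // 4
    parts = [
        _roll(x[:, 0 * q : 1 * q], s, axis=2),
        _roll(x[:, 1 * q : 2 * q], -s, axis=2),
        _roll(x[:, 2 * q : 3 * q], s, axis=3),
        _roll(x[:, 3 * q : 4 * q], -s, axis=3),
    ]
    return anp.concatenate(parts, axis=1)


@dataclass(frozen=True)
class SCAUConfig:
    channels_in: int
    channels_out: int = 0  # 0 -> channels_in
    s: int = 1
    g: int = 4

    def __post_init__(self):
        object.__setattr__(self, "channels_out", self.channels_out or self.channels_in)
        if self.channels_in % 4:
            raise ValueError("SCAU requires input channels divisible by 4")
        if self.channels_in % self.g:
            raise ValueError("SCAU groups must divide the channel count")


class SCAUBlock(nn.Module):
    """2x upsample -> depthwise-separable conv -> channel shuffle ->
    MDFS -> pointwise conv (+ BN + SiLU)."""

    def __init__(self, cfg: SCAUConfig):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels_in
        self.dw = nn.DWConv(c, 3)
        self.pw1 = nn.ConvBNAct(c, c, 1)
        self.pw2 = nn.ConvBNAct(c, cfg.channels_out, 1)

    def forward(self, x, p):
        B, C, H, W = check_feature_map(x)
        if C != self.cfg.channels_in:
            raise ValueError(f"expected {self.cfg.channels_in} channels, got {C}")
        y = nn.functional.interpolate(x, (2 * H, 2 * W), mode="nearest")
        y = self.pw1(self.dw(y, p["dw"]), p["pw1"])
        y = channel_shuffle(y, self.cfg.g)
        y = mdfs(y, ShiftSpec(self.cfg.s))
        return self.pw2(y, p["pw2"])


def scau_forward(x, block: SCAUBlock):
    return block(x)
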