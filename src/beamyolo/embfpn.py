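"""Enhanced Multi-scale Bidirectional Feature Pyramid Network (EM-BFPN).

The neck unifies P3/P4/P5 channels with 1x1 convs, runs a top-down and a
bottom-up pass, fuses at every junction with a learnable nonnegative
weighted average (AFFM), and enhances each fused map with a CSP-style
multi-kernel depthwise block (MSCM).  Per-level depthwise kernel sets
grow with the receptive field: {1,3,5} at P3, {3,5,7} at P4, {5,7,9} at
P5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence, Tuple

import autograd.numpy as anp
import numpy as np

from . import nn
from .men import check_feature_map
from .nn import functional as F
from .scau import SCAUBlock, SCAUConfig

AFFM_EPS = 1e-4


class AFFMFuse(nn.Module):
    """Adaptive feature fusion: out = sum_i relu(w_i) F_i / (sum_j relu(w_j) + eps).

    Raw weights initialize to 1 so fusion starts as an eps-discounted
    average; ReLU keeps contributions nonnegative so features cannot
    cancel each other.
    """

    def __init__(self, n_inputs: int):
        super().__init__()
        if n_inputs < 1:
            raise ValueError("AFFM needs at least one input")
        self.n_inputs = n_inputs
        self.add_param("raw", np.ones(n_inputs))

    def forward(self, features, p):
        if len(features) != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} features, got {len(features)}")
        shapes = {np.shape(f) for f in features}
        if len(shapes) != 1:
            raise ValueError(f"AFFM inputs must share shape, got {shapes}")
        w = anp.maximum(p["raw"], 0.0)
        denom = anp.sum(w) + AFFM_EPS
        out = 0.0
        for i, f in enumerate(features):
            out = out + w[i] * f
        F.matmul_count(*np.shape(features[0]), len(features))
        return out / denom


def affm_fuse(features: Sequence, raw_weights: Sequence[float]):
    """Functional AFFM with explicit raw weights."""
    m = AFFMFuse(len(raw_weights))
    return m(list(features), {"raw": np.asarray(raw_weights, dtype=float)})


@dataclass(frozen=True)
class MSCMConfig:
    in_channels: int
    out_channels: int
    expansion: float = 0.5
    n_blocks: int = 1
    kernel_set: Tuple[int, ...] = (1, 3, 5)
    stride: int = 1

    def __post_init__(self):
        if any(k % 2 == 0 or k < 1 for k in self.kernel_set):
            raise ValueError(f"kernel sizes must be odd and positive: {self.kernel_set}")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if (self.in_channels * self.expansion) % 2:
            raise ValueError("expansion * in_channels must be even")


class PRFFM(nn.Module):
    """Parallel receptive-field fusion: one depthwise conv (+BN+ReLU) per
    kernel size, all preserving spatial dims; branch outputs are summed
    by the caller."""

    def __init__(self, channels: int, kernel_set: Tuple[int, ...], stride: int = 1):
        super().__init__()
        self.kernel_set = tuple(kernel_set)
        for k in self.kernel_set:
            if k % 2 == 0:
                raise ValueError(f"even kernel {k} not allowed")
            setattr(self, f"k{k}", nn.ConvBNAct(channels, channels, k, stride=stride,
                                                groups=channels, act="relu"))

    def forward(self, x, p):
        check_feature_map(x)
        return [getattr(self, f"k{k}")(x, p[f"k{k}"]) for k in self.kernel_set]


class DSARB(nn.Module):
    """Depthwise scale-adaptive residual block:
    y = proj(shuffle(sum(PRFFM(expand(x))))) [+ x when stride 1]."""

    def __init__(self, cfg: MSCMConfig):
        super().__init__()
        self.cfg = cfg
        e_ch = int(round(cfg.in_channels * cfg.expansion))
        e_ch = max(4, e_ch + (-e_ch) % 4)  # keep shuffle groups valid
        self.e_ch = e_ch
        self.expand = nn.ConvBNAct(cfg.in_channels, e_ch, 1)
        self.branches = PRFFM(e_ch, cfg.kernel_set, stride=cfg.stride)
        self.proj = nn.Conv2d(e_ch, cfg.out_channels, 1)
        self.bn = nn.BatchNorm2d(cfg.out_channels)
        self.residual = cfg.stride == 1
        if self.residual and cfg.in_channels != cfg.out_channels:
            self.res = nn.Conv2d(cfg.in_channels, cfg.out_channels, 1)
            self.has_res_conv = True
        else:
            self.has_res_conv = False

    def forward(self, x, p):
        check_feature_map(x)
        y = self.expand(x, p["expand"])
        outs = self.branches(y, p["branches"])
        agg = outs[0]
        for o in outs[1:]:
            agg = agg + o
        from .scau import channel_shuffle  # local to avoid cycle at import time

        agg = channel_shuffle(agg, 4)
        y = self.bn(self.proj(agg, p["proj"]), p["bn"])
        if self.residual:
            shortcut = self.res(x, p["res"]) if self.has_res_conv else x
            y = y + shortcut
        return y


class MSCM(nn.Module):
    """CSP wrapper: two 1x1 entry paths at width in_channels * e / 2, a
    chain of n DSARB on the processed path, concat, 1x1 exit conv."""

    def __init__(self, cfg: MSCMConfig):
        super().__init__()
        self.cfg = cfg
        c = int(round(cfg.in_channels * cfg.expansion / 2))
        c = max(4, c + (-c) % 4)
        self.phi1 = nn.ConvBNAct(cfg.in_channels, c, 1)
        self.phi3 = nn.ConvBNAct(cfg.in_channels, c, 1)
        for i in range(cfg.n_blocks):
            setattr(self, f"b{i}", DSARB(MSCMConfig(c, c, 1.0, 0, cfg.kernel_set, 1)))
        self.phi2 = nn.ConvBNAct(c, c, 1)
        self.exit = nn.ConvBNAct(2 * c, cfg.out_channels, 1)

    def forward(self, x, p):
        check_feature_map(x)
        a = self.phi1(x, p["phi1"])
        b = self.phi3(x, p["phi3"])
        for i in range(self.cfg.n_blocks):
            b = getattr(self, f"b{i}")(b, p[f"b{i}"])
        b = self.phi2(b, p["phi2"])
        return self.exit(anp.concatenate([a, b], axis=1), p["exit"])


class PyramidLevels(NamedTuple):
    p3: np.ndarray
    p4: np.ndarray
    p5: np.ndarray

    def validate(self) -> "PyramidLevels":
        s3, s4, s5 = (np.shape(t) for t in self)
        if s4[2:] != (s3[2] // 2, s3[3] // 2) or s5[2:] != (s3[2] // 4, s3[3] // 4):
            raise ValueError(
                f"pyramid geometry must halve per level, got {s3[2:]} {s4[2:]} {s5[2:]}"
            )
        return self


KERNEL_SETS = {"p3": (1, 3, 5), "p4": (3, 5, 7), "p5": (5, 7, 9)}


class EMBFPNNeck(nn.Module):
    """Bidirectional weighted-fusion neck over P3/P4/P5.

    Top-down junctions fuse two inputs (upsampled upper level + lateral);
    bottom-up junctions fuse three (downsampled lower level, the
    top-down result, and the preprocessed lateral).  Upsampling uses
    nearest-neighbour interpolation, or SCAU blocks when enabled.
    """

    def __init__(self, in_channels: Tuple[int, int, int], width: int = 64,
                 expansion: float = 0.5, n_blocks: int = 1, use_scau: bool = False):
        super().__init__()
        self.width = width
        self.use_scau = use_scau
        c3, c4, c5 = in_channels
        self.pre3 = nn.ConvBNAct(c3, width, 1)
        self.pre4 = nn.ConvBNAct(c4, width, 1)
        self.pre5 = nn.ConvBNAct(c5, width, 1)
        if use_scau:
            self.up5 = SCAUBlock(SCAUConfig(width))
            self.up4 = SCAUBlock(SCAUConfig(width))
        self.fuse_td4 = AFFMFuse(2)
        self.fuse_td3 = AFFMFuse(2)
        self.mscm_td4 = MSCM(MSCMConfig(width, width, expansion, n_blocks, KERNEL_SETS["p4"]))
        self.mscm_p3 = MSCM(MSCMConfig(width, width, expansion, n_blocks, KERNEL_SETS["p3"]))
        self.down3 = nn.ConvBNAct(width, width, 3, stride=2)
        self.down4 = nn.ConvBNAct(width, width, 3, stride=2)
        self.fuse_bu4 = AFFMFuse(3)
        self.fuse_bu5 = AFFMFuse(2)
        self.mscm_p4 = MSCM(MSCMConfig(width, width, expansion, n_blocks, KERNEL_SETS["p4"]))
        self.mscm_p5 = MSCM(MSCMConfig(width, width, expansion, n_blocks, KERNEL_SETS["p5"]))

    def _up(self, x, which, p):
        if self.use_scau:
            return getattr(self, which)(x, p[which])
        B, C, H, W = x.shape
        return F.interpolate(x, (2 * H, 2 * W), mode="nearest")

    def forward(self, levels: PyramidLevels, p):
        levels = PyramidLevels(*levels).validate()
        l3 = self.pre3(levels.p3, p["pre3"])
        l4 = self.pre4(levels.p4, p["pre4"])
        l5 = self.pre5(levels.p5, p["pre5"])
        # top-down
        td4 = self.mscm_td4(self.fuse_td4([self._up(l5, "up5", p), l4], p["fuse_td4"]),
                            p["mscm_td4"])
        out3 = self.mscm_p3(self.fuse_td3([self._up(td4, "up4", p), l3], p["fuse_td3"]),
                            p["mscm_p3"])
        # bottom-up
        bu4 = self.fuse_bu4([self.down3(out3, p["down3"]), td4, l4], p["fuse_bu4"])
        out4 = self.mscm_p4(bu4, p["mscm_p4"])
        bu5 = self.fuse_bu5([self.down4(out4, p["down4"]), l5], p["fuse_bu5"])
        out5 = self.mscm_p5(bu5, p["mscm_p5"])
        return PyramidLevels(out3, out4, out5)

    @property
    def out_channels(self) -> Tuple[int, int, int]:
        return (self.width, self.width, self.width)


def build_neck(levels: PyramidLevels, neck: EMBFPNNeck) -> PyramidLevels:
    return neck(levels)


def dsarb(x, cfg: MSCMConfig):
    return DSARB(cfg)(x)


def mscm(x, cfg: MSCMConfig):
    return MSCM(cfg)(x)


def prffm(x, kernel_set: Tuple[int, ...]):
    c = np.shape(x)[1]
    return PRFFM(c, tuple(kernel_set))(x)
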