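"""Bifurcated Attention Feature Enhancement (BAFE).

A frozen single-level Haar decomposition splits features into one
low-frequency (approximation) and three high-frequency subbands at half
resolution.  High-frequency energy guides a foreground windowed
attention stage; the low-frequency band guides a second, cascaded
background stage.  The four 2x2 Haar filters (each scaled by 1/2) form
an orthonormal basis of 2x2 blocks, so the decomposition conserves
energy and is exactly invertible on even-sized inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import autograd.numpy as anp
import numpy as np

from . import nn
from .men import check_feature_map
from .nn import functional as F

# 1/2-scaled Haar analysis filters: approximation, horizontal, vertical,
# diagonal.  Rows of each 2x2 grid index image rows (height).
HAAR_A = 0.5 * np.array([[1.0, 1.0], [1.0, 1.0]])
HAAR_H = 0.5 * np.array([[-1.0, -1.0], [1.0, 1.0]])
HAAR_V = 0.5 * np.array([[-1.0, 1.0], [-1.0, 1.0]])
HAAR_D = 0.5 * np.array([[1.0, -1.0], [-1.0, 1.0]])
_HAAR_STACK = np.stack([HAAR_A, HAAR_H, HAAR_V, HAAR_D])  # (4,2,2)


class HaarFilterBank:
    """The four frozen 2x2 analysis filters; never trained."""

    def __init__(self) -> None:
        self.filters = _HAAR_STACK.copy()
        self.trainable = False

    def gram(self) -> np.ndarray:
        flat = self.filters.reshape(4, -1)
        return flat @ flat.T

    @property
    def num_coefficients(self) -> int:
        return self.filters.size


class SubbandSet(NamedTuple):
    approx: np.ndarray
    horiz: np.ndarray
    vert: np.ndarray
    diag: np.ndarray

    def validate(self):
        shapes = {np.shape(s) for s in self}
        if len(shapes) != 1:
            raise ValueError(f"subband shapes differ: {shapes}")
        return self


def haar_decompose(x) -> SubbandSet:
    """Per-channel stride-2, no-padding convolution with the frozen Haar
    filters.  Odd trailing rows/columns are dropped (floor semantics)."""
    B, C, H, W = check_feature_map(x)
    if H < 2 or W < 2:
        raise ValueError(f"haar_decompose needs H, W >= 2, got {(H, W)}")
    oh, ow = H // 2, W // 2
    x = x[:, :, : 2 * oh, : 2 * ow]
    # stride-2 2x2 conv == weighted sum of the four polyphase components
    p00 = x[:, :, 0::2, 0::2]
    p01 = x[:, :, 0::2, 1::2]
    p10 = x[:, :, 1::2, 0::2]
    p11 = x[:, :, 1::2, 1::2]
    F.matmul_count(B * C * oh * ow, 16)
    bands = []
    for f in (HAAR_A, HAAR_H, HAAR_V, HAAR_D):
        bands.append(f[0, 0] * p00 + f[0, 1] * p01 + f[1, 0] * p10 + f[1, 1] * p11)
    return SubbandSet(*bands)


def haar_reconstruct(s: SubbandSet):
    """Exact inverse of :func:`haar_decompose` on even-sized inputs
    (adjoint of the orthonormal 2x2 block transform)."""
    s.validate()
    a, h, v, d = s
    B, C, oh, ow = np.shape(a)
    comps = {}
    for (i, j) in ((0, 0), (0, 1), (1, 0), (1, 1)):
        comps[(i, j)] = (HAAR_A[i, j] * a + HAAR_H[i, j] * h
                         + HAAR_V[i, j] * v + HAAR_D[i, j] * d)
    rows0 = anp.stack([comps[(0, 0)], comps[(0, 1)]], axis=4)  # (B,C,oh,ow,2)
    rows1 = anp.stack([comps[(1, 0)], comps[(1, 1)]], axis=4)
    inter = anp.stack([rows0, rows1], axis=3)  # (B,C,oh,2,ow,2)
    return anp.reshape(inter, (B, C, 2 * oh, 2 * ow))


def subband_fuse(s: SubbandSet):
    """(f_high, f_low): sum of the three detail bands, and the
    approximation band."""
    s.validate()
    return s.horiz + s.vert + s.diag, s.approx


class WindowedAttention(nn.Module):
    """Window-local multi-head attention over k x k neighbourhoods.

    Queries and keys come from a guide map (a pooled frequency band);
    values from the feature being refined.  For every spatial position a
    k x k window (stride 1, zero padding) is unfolded; attention weights
    A = softmax(QK^T / sqrt(d_h) + bias) have shape (B, heads, L, k^2, k^2)
    and each row is a probability vector.  The output keeps the value
    map's spatial dims by reading each window at its centre slot.
    """

    def __init__(self, guide_channels: int, channels: int, heads: int = 4, k: int = 3):
        super().__init__()
        if channels % heads:
            raise ValueError(f"channels {channels} not divisible by {heads} heads")
        if k % 2 == 0:
            raise ValueError("window size k must be odd")
        self.heads, self.k = heads, k
        self.dh = channels // heads
        self.q = nn.Conv2d(guide_channels, channels, 1)
        self.key = nn.Conv2d(guide_channels, channels, 1)
        self.v = nn.Conv2d(channels, channels, 1)
        self.proj = nn.ConvBNAct(channels, channels, 1)
        # learned relative position bias per head, zero init so attention
        # starts uniform
        self.add_param("pos_bias", np.zeros((heads, k * k, k * k)))

    def _split_windows(self, t, B, H, W):
        kk = self.k * self.k
        w = F.unfold_windows(t, self.k)  # (B,C,kk,L)
        w = anp.reshape(w, (B, self.heads, self.dh, kk, H * W))
        return anp.transpose(w, (0, 1, 4, 3, 2))  # (B,heads,L,kk,dh)

    def attention_weights(self, guide, p):
        B, Cg, H, W = check_feature_map(guide)
        if self.k > min(H, W):
            raise ValueError(f"window {self.k} exceeds spatial extent {(H, W)}")
        q = self._split_windows(self.q(guide, p["q"]), B, H, W)
        k = self._split_windows(self.key(guide, p["key"]), B, H, W)
        kk = self.k * self.k
        logits = anp.einsum("bnlid,bnljd->bnlij", q, k) / np.sqrt(self.dh)
        F.matmul_count(B * self.heads * H * W, kk * kk, self.dh)
        logits = logits + p["pos_bias"][None, :, None]
        return F.softmax(logits, axis=-1)

    def forward(self, inputs, p):
        guide, v = inputs
        B, C, H, W = check_feature_map(v)
        if np.shape(guide)[2:] != (H, W):
            raise ValueError("guide and value maps must share spatial dims")
        a = self.attention_weights(guide, p)
        vals = self._split_windows(self.v(v, p["v"]), B, H, W)
        kk = self.k * self.k
        out = anp.einsum("bnlij,bnljd->bnlid", a, vals)
        F.matmul_count(B * self.heads * H * W, kk * kk, self.dh)
        centre = out[:, :, :, kk // 2, :]  # (B,heads,L,dh)
        centre = anp.reshape(anp.transpose(centre, (0, 1, 3, 2)), (B, C, H, W))
        return self.proj(centre, p["proj"])


@dataclass(frozen=True)
class BAFEConfig:
    channels: int
    out_channels: int = 0  # 0 -> channels
    mid_channels: int = 0  # 0 -> 2 * channels
    heads: int = 4
    window: int = 3
    pool: int = 2

    def __post_init__(self):
        object.__setattr__(self, "out_channels", self.out_channels or self.channels)
        object.__setattr__(self, "mid_channels", self.mid_channels or 2 * self.channels)


class BAFEBlock(nn.Module):
    """Frequency-guided cascaded attention block replacing the baseline's
    terminal attention stage.

    Pipeline: 1x1 preprocessing -> Haar decomposition -> subband fusion
    -> average-pool downsample of the two frequency guides -> foreground
    attention guided by the high band -> background attention guided by
    the low band applied to the foreground output -> 1x1 projection,
    with a residual shortcut when the widths agree.
    """

    def __init__(self, cfg: BAFEConfig):
        super().__init__()
        self.cfg = cfg
        m = cfg.mid_channels
        self.pre = nn.ConvBNAct(cfg.channels, m, 1)
        self.fg = WindowedAttention(m, m, cfg.heads, cfg.window)
        self.bg = WindowedAttention(m, m, cfg.heads, cfg.window)
        self.post = nn.ConvBNAct(m, cfg.out_channels, 1)
        self.filter_bank = HaarFilterBank()

    def frozen_param_count(self) -> int:
        return self.filter_bank.num_coefficients

    def forward(self, x, p):
        B, C, H, W = check_feature_map(x)
        h = self.pre(x, p["pre"])
        bands = haar_decompose(h)
        f_high, f_low = subband_fuse(bands)
        pool = self.cfg.pool
        if pool > 1 and min(f_high.shape[2:]) >= pool:
            f_high = F.avg_pool2d(f_high, pool)
            f_low = F.avg_pool2d(f_low, pool)
        g_high = F.interpolate(f_high, (H, W), mode="nearest")
        g_low = F.interpolate(f_low, (H, W), mode="nearest")
        x_fg = self.fg((g_high, h), p["fg"])
        x_bg = self.bg((g_low, x_fg), p["bg"])
        y = self.post(x_bg, p["post"])
        if self.cfg.channels == self.cfg.out_channels:
            y = y + x
        return y


def bafe_forward(x, block: BAFEBlock):
    return block(x)
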