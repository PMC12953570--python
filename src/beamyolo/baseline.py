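"""Baseline single-stage detector building blocks.

Reconstruction of the YOLOv11-family nano topology: a conv stem, four
CSP stages (C3k2), SPPF, a terminal partial spatial-attention block
(C2PSA), a PAN-style neck, and an anchor-free decoupled head with
distribution-focal box regression (reg_max bins per side).
"""

from __future__ import annotations

from typing import Tuple

import autograd.numpy as anp
import numpy as np

from . import nn
from .nn import functional as F


class Bottleneck(nn.Module):
    def __init__(self, c1, c2, shortcut=True, e=0.5, k=(3, 3)):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = nn.ConvBNAct(c1, c_, k[0])
        self.cv2 = nn.ConvBNAct(c_, c2, k[1])
        self.add = shortcut and c1 == c2

    def forward(self, x, p):
        y = self.cv2(self.cv1(x, p["cv1"]), p["cv2"])
        return x + y if self.add else y


class C3k(nn.Module):
    """CSP block with two serial bottlenecks on the processed path."""

    def __init__(self, c1, c2, n=2, shortcut=True):
        super().__init__()
        c_ = c2 // 2
        self.cv1 = nn.ConvBNAct(c1, c_, 1)
        self.cv2 = nn.ConvBNAct(c1, c_, 1)
        self.m = nn.Sequential(*[Bottleneck(c_, c_, shortcut, e=1.0) for _ in range(n)])
        self.cv3 = nn.ConvBNAct(2 * c_, c2, 1)

    def forward(self, x, p):
        a = self.m(self.cv1(x, p["cv1"]), p["m"])
        b = self.cv2(x, p["cv2"])
        return self.cv3(anp.concatenate([a, b], axis=1), p["cv3"])


class C3k2(nn.Module):
    """Fast CSP stage: split after a 1x1 conv, n processed chunks appended
    and fused (the C2f pattern, with C3k inner blocks when ``c3k``)."""

    def __init__(self, c1, c2, n=1, c3k=False, e=0.5, shortcut=True):
        super().__init__()
        self.c = int(c2 * e)
        self.n = n
        self.cv1 = nn.ConvBNAct(c1, 2 * self.c, 1)
        self.cv2 = nn.ConvBNAct((2 + n) * self.c, c2, 1)
        for i in range(n):
            blk = C3k(self.c, self.c, 2, shortcut) if c3k else Bottleneck(self.c, self.c, shortcut)
            setattr(self, f"m{i}", blk)

    def forward(self, x, p):
        y = self.cv1(x, p["cv1"])
        parts = [y[:, : self.c], y[:, self.c :]]
        for i in range(self.n):
            parts.append(getattr(self, f"m{i}")(parts[-1], p[f"m{i}"]))
        return self.cv2(anp.concatenate(parts, axis=1), p["cv2"])


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three serial 5x5 stride-1 max pools."""

    def __init__(self, c1, c2, k=5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = nn.ConvBNAct(c1, c_, 1)
        self.cv2 = nn.ConvBNAct(c_ * 4, c2, 1)
        self.k = k

    def forward(self, x, p):
        y = [self.cv1(x, p["cv1"])]
        for _ in range(3):
            y.append(F.max_pool2d(y[-1], self.k, 1, self.k // 2))
        return self.cv2(anp.concatenate(y, axis=1), p["cv2"])


class PSAAttention(nn.Module):
    """Global multi-head self-attention with a depthwise positional conv."""

    def __init__(self, dim, num_heads=2, attn_ratio=0.5):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        nh_kd = self.key_dim * num_heads
        self.qkv = nn.ConvBNAct(dim, dim + 2 * nh_kd, 1, act=None)
        self.proj = nn.ConvBNAct(dim, dim, 1, act=None)
        self.pe = nn.ConvBNAct(dim, dim, 3, groups=dim, act=None)

    def forward(self, x, p):
        B, C, H, W = x.shape
        N = H * W
        qkv = self.qkv(x, p["qkv"])
        kd, hd = self.key_dim, self.head_dim
        qkv = anp.reshape(qkv, (B, self.num_heads, 2 * kd + hd, N))
        q, k, v = qkv[:, :, :kd], qkv[:, :, kd : 2 * kd], qkv[:, :, 2 * kd :]
        attn = anp.einsum("bhdn,bhdm->bhnm", q, k) / np.sqrt(kd)
        F.matmul_count(B * self.num_heads, N * N, kd)
        attn = F.softmax(attn, axis=-1)
        out = anp.einsum("bhdm,bhnm->bhdn", v, attn)
        F.matmul_count(B * self.num_heads, N * N, hd)
        out = anp.reshape(out, (B, C, H, W))
        vmap = anp.reshape(v, (B, C, H, W))
        out = out + self.pe(vmap, p["pe"])
        return self.proj(out, p["proj"])


class PSABlock(nn.Module):
    def __init__(self, c, num_heads):
        super().__init__()
        self.attn = PSAAttention(c, num_heads)
        self.ffn = nn.Sequential(nn.ConvBNAct(c, c * 2, 1), nn.ConvBNAct(c * 2, c, 1, act=None))

    def forward(self, x, p):
        x = x + self.attn(x, p["attn"])
        return x + self.ffn(x, p["ffn"])


class C2PSA(nn.Module):
    def __init__(self, c1, c2, n=1, e=0.5):
        super().__init__()
        self.c = int(c1 * e)
        self.cv1 = nn.ConvBNAct(c1, 2 * self.c, 1)
        self.cv2 = nn.ConvBNAct(2 * self.c, c2, 1)
        self.m = nn.Sequential(*[PSABlock(self.c, max(self.c // 64, 1)) for _ in range(n)])

    def forward(self, x, p):
        y = self.cv1(x, p["cv1"])
        a, b = y[:, : self.c], y[:, self.c :]
        b = self.m(b, p["m"])
        return self.cv2(anp.concatenate([a, b], axis=1), p["cv2"])


class DetectHead(nn.Module):
    """Decoupled anchor-free head over three pyramid levels.

    Per level: a box branch emitting 4 * reg_max distribution-focal
    logits and a (depthwise-separable) classification branch emitting
    ``nc`` class logits.
    """

    def __init__(self, nc: int, ch: Tuple[int, int, int], reg_max: int = 16):
        super().__init__()
        self.nc, self.reg_max = nc, reg_max
        self.strides = (8, 16, 32)
        c2 = max(16, ch[0] // 4, 4 * reg_max)
        c3 = max(ch[0], min(nc, 100))
        for i, c in enumerate(ch):
            box = nn.Sequential(
                nn.ConvBNAct(c, c2, 3), nn.ConvBNAct(c2, c2, 3),
                nn.Conv2d(c2, 4 * reg_max, 1, bias=True))
            cls = nn.Sequential(
                nn.DWConv(c, 3), nn.ConvBNAct(c, c3, 1),
                nn.DWConv(c3, 3), nn.ConvBNAct(c3, c3, 1),
                nn.Conv2d(c3, nc, 1, bias=True))
            # prior initialization: rare-positive class logits, unit box bias
            box[-1].add_param("bias", np.full(4 * reg_max, 1.0))
            cls[-1].add_param("bias", np.full(nc, -np.log((1 - 0.01) / 0.01)))
            setattr(self, f"box{i}", box)
            setattr(self, f"cls{i}", cls)

    def forward(self, feats, p):
        outs = []
        for i, f in enumerate(feats):
            box = getattr(self, f"box{i}")(f, p[f"box{i}"])
            cls = getattr(self, f"cls{i}")(f, p[f"cls{i}"])
            outs.append((box, cls))
        return outs
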