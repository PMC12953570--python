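"""Standard layers: conv + norm + activation, pooling, resampling.

Construction draws initial weights from a process-wide generator seeded
via :func:`seed_init`, so identical configs and seeds build bit-identical
models.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from . import functional as F
from .core import Module, Sequential, kaiming_uniform

_init_rng = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Reset the weight-initialization stream (call before building)."""
    global _init_rng
    _init_rng = np.random.default_rng(seed)


def init_rng() -> np.random.Generator:
    return _init_rng


class Conv2d(Module):
    def __init__(self, c_in, c_out, k=1, stride=1, padding=None, groups=1, bias=False):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = (c_in // groups) * k * k
        self.add_param("weight", kaiming_uniform(_init_rng, (c_out, c_in // groups, k, k), fan_in))
        if bias:
            self.add_param("bias", np.zeros(c_out))
        self.has_bias = bias

    def forward(self, x, p):
        return F.conv2d(x, p["weight"], p.get("bias") if self.has_bias else None,
                        stride=self.stride, padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel.

    Training mode normalizes by batch statistics (differentiable) and
    updates running moments as a side effect outside the gradient tape;
    eval mode uses the running moments.
    """

    def __init__(self, c, eps=1e-5, momentum=0.03):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.add_param("gamma", np.ones(c))
        self.add_param("beta", np.zeros(c))
        self.add_buffer("running_mean", np.zeros(c))
        self.add_buffer("running_var", np.ones(c))

    def forward(self, x, p):
        if self.training:
            mean = anp.mean(x, axis=(0, 2, 3))
            var = anp.var(x, axis=(0, 2, 3))
            m = self.momentum
            self.set_buffer("running_mean", (1 - m) * self._buffers["running_mean"] + m * mean)
            self.set_buffer("running_var", (1 - m) * self._buffers["running_var"] + m * var)
        else:
            mean, var = self._buffers["running_mean"], self._buffers["running_var"]
        return F.batch_norm(x, p["gamma"], p["beta"], mean, var, self.eps)


class SiLU(Module):
    def forward(self, x, p):
        return F.silu(x)


class ReLU(Module):
    def forward(self, x, p):
        return F.relu(x)


class ConvBNAct(Module):
    """conv -> batch norm -> activation, the network's workhorse block."""

    def __init__(self, c_in, c_out, k=1, stride=1, padding=None, groups=1, act="silu"):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, stride, padding, groups)
        self.bn = BatchNorm2d(c_out)
        self.act = act

    def forward(self, x, p):
        y = self.bn(self.conv(x, p["conv"]), p["bn"])
        if self.act == "silu":
            return F.silu(y)
        if self.act == "relu":
            return F.relu(y)
        return y


class DWConv(ConvBNAct):
    """Depthwise conv + BN + activation (groups = channels)."""

    def __init__(self, c, k=3, stride=1, act="silu"):
        super().__init__(c, c, k, stride, groups=c, act=act)


class MaxPool2d(Module):
    def __init__(self, k, stride=1, padding=None):
        super().__init__()
        self.k, self.stride = k, stride
        self.padding = k // 2 if padding is None else padding

    def forward(self, x, p):
        return F.max_pool2d(x, self.k, self.stride, self.padding)


class Upsample(Module):
    def __init__(self, scale=2, mode="nearest"):
        super().__init__()
        self.scale, self.mode = scale, mode

    def forward(self, x, p):
        B, C, H, W = x.shape
        return F.interpolate(x, (H * self.scale, W * self.scale), mode=self.mode)


__all__ = [
    "Conv2d", "BatchNorm2d", "ConvBNAct", "DWConv", "SiLU", "ReLU",
    "MaxPool2d", "Upsample", "Sequential", "seed_init", "init_rng",
]
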