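"""Differentiable array primitives for (B, C, H, W) feature maps.

All ops are written against ``autograd.numpy`` so that reverse-mode
differentiation works end to end; when no gradient tape is active they
run on plain numpy arrays with zero overhead beyond the dispatch.

A thread-local FLOP counter can be armed with :class:`FlopCounter`;
primitives then report their cost using the 2x multiply-accumulate
convention for contractions and one op per element for pointwise work.
"""

from __future__ import annotations

import threading

import autograd.numpy as anp
import numpy as np

_tls = threading.local()


class FlopCounter:
    """Context manager accumulating floating point operation counts.

    Convolutions and matrix contractions count 2 ops per MAC; elementwise
    ops count one per output element; normalization counts two (scale and
    shift).  Only one counter may be armed at a time per thread.
    """

    def __init__(self) -> None:
        self.total = 0

    def add(self, n: int) -> None:
        self.total += int(n)

    def __enter__(self) -> "FlopCounter":
        _tls.counter = self
        return self

    def __exit__(self, *exc) -> None:
        _tls.counter = None


def _count(n: int) -> None:
    c = getattr(_tls, "counter", None)
    if c is not None:
        c.add(n)


# ---------------------------------------------------------------------------
# shape helpers


def conv_out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _as_pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


# ---------------------------------------------------------------------------
# convolution


def conv2d(x, w, b=None, stride=1, padding=0, groups=1):
    """2-D cross-correlation over BCHW input.

    ``w`` has shape (C_out, C_in // groups, kh, kw).  Implemented as a sum
    of kh*kw shifted-slice contractions, which keeps the whole computation
    inside BLAS and is traceable by autograd (no scatter ops).
    """
    B, C, H, W = x.shape
    Co, Cg, kh, kw = w.shape
    sh, sw = _as_pair(stride)
    ph, pw = _as_pair(padding)
    if C != Cg * groups:
        raise ValueError(f"conv2d: {C} input channels, weight expects {Cg * groups}")
    OH = conv_out_size(H, kh, sh, ph)
    OW = conv_out_size(W, kw, sw, pw)
    if OH < 1 or OW < 1:
        raise ValueError(f"conv2d: spatial dims {(H, W)} too small for kernel {(kh, kw)}")
    xp = anp.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), "constant") if (ph or pw) else x

    if groups == C and Cg == 1:  # depthwise fast path
        out = 0.0
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + OH * sh : sh, j : j + OW * sw : sw]
                out = out + xs * w[:, 0, i, j][None, :, None, None]
        _count(2 * B * C * kh * kw * OH * OW)
    elif groups == 1:
        acc = 0.0
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + OH * sh : sh, j : j + OW * sw : sw]
                # (B,OH,OW,Co) accumulation, transposed once at the end
                acc = acc + anp.tensordot(xs, w[:, :, i, j], axes=([1], [1]))
        out = anp.moveaxis(acc, 3, 1)
        _count(2 * B * Co * C * kh * kw * OH * OW)
    else:
        if C % groups or Co % groups:
            raise ValueError("conv2d: channels not divisible by groups")
        cg_o = Co // groups
        outs = []
        for g in range(groups):
            xg = xp[:, g * Cg : (g + 1) * Cg]
            wg = w[g * cg_o : (g + 1) * cg_o]
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    xs = xg[:, :, i : i + OH * sh : sh, j : j + OW * sw : sw]
                    acc = acc + anp.tensordot(xs, wg[:, :, i, j], axes=([1], [1]))
            outs.append(anp.moveaxis(acc, 3, 1))
        out = anp.concatenate(outs, axis=1)
        _count(2 * B * Co * Cg * kh * kw * OH * OW)

    if b is not None:
        out = out + b[None, :, None, None]
        _count(B * Co * OH * OW)
    return out


# ---------------------------------------------------------------------------
# activations / normalization


def sigmoid(x):
    _count(4 * _numel(x))
    return 1.0 / (1.0 + anp.exp(-x))


def silu(x):
    _count(5 * _numel(x))
    return x / (1.0 + anp.exp(-x))


def relu(x):
    _count(_numel(x))
    return anp.maximum(x, 0.0)


def softmax(x, axis=-1):
    _count(5 * _numel(x))
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def softplus(x):
    _count(4 * _numel(x))
    return anp.log1p(anp.exp(-anp.abs(x))) + anp.maximum(x, 0.0)


def batch_norm(x, gamma, beta, mean, var, eps=1e-5):
    _count(2 * _numel(x))
    inv = 1.0 / anp.sqrt(var + eps)
    return (x - mean[None, :, None, None]) * (gamma * inv)[None, :, None, None] + beta[
        None, :, None, None
    ]


def _numel(x) -> int:
    n = 1
    for s in x.shape:
        n *= s
    return n


# ---------------------------------------------------------------------------
# pooling


def avg_pool2d(x, k, stride=None, padding=0, pad_mode="constant"):
    """Average pooling; ``pad_mode='edge'`` replicates borders (same-size
    local smoothing as used by the edge enhancer)."""
    kh, kw = _as_pair(k)
    stride = stride if stride is not None else k
    sh, sw = _as_pair(stride)
    ph, pw = _as_pair(padding)
    B, C, H, W = x.shape
    if ph or pw:
        if pad_mode == "edge":
            x = anp.concatenate([anp.repeat(x[:, :, :1], ph, axis=2), x,
                                 anp.repeat(x[:, :, -1:], ph, axis=2)], axis=2)
            x = anp.concatenate([anp.repeat(x[:, :, :, :1], pw, axis=3), x,
                                 anp.repeat(x[:, :, :, -1:], pw, axis=3)], axis=3)
        else:
            x = anp.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), "constant")
    H2, W2 = x.shape[2], x.shape[3]
    OH = (H2 - kh) // sh + 1
    OW = (W2 - kw) // sw + 1
    if OH < 1 or OW < 1:
        raise ValueError(f"avg_pool2d: input {(H, W)} smaller than window {(kh, kw)}")
    out = 0.0
    for i in range(kh):
        for j in range(kw):
            out = out + x[:, :, i : i + OH * sh : sh, j : j + OW * sw : sw]
    _count(B * C * OH * OW * (kh * kw + 1))
    return out / (kh * kw)


def max_pool2d(x, k, stride=1, padding=0):
    kh, kw = _as_pair(k)
    sh, sw = _as_pair(stride)
    ph, pw = _as_pair(padding)
    B, C, H, W = x.shape
    if ph or pw:
        x = anp.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), "constant", constant_values=-anp.inf)
    OH = (x.shape[2] - kh) // sh + 1
    OW = (x.shape[3] - kw) // sw + 1
    out = None
    for i in range(kh):
        for j in range(kw):
            xs = x[:, :, i : i + OH * sh : sh, j : j + OW * sw : sw]
            out = xs if out is None else anp.maximum(out, xs)
    _count(B * C * OH * OW * kh * kw)
    return out


def pool_matrix(in_size: int, out_size: int) -> np.ndarray:
    """Row-stochastic (out, in) matrix realizing adaptive average pooling
    with the standard floor/ceil window partition."""
    m = np.zeros((out_size, in_size))
    for i in range(out_size):
        a = (i * in_size) // out_size
        b = -(-((i + 1) * in_size) // out_size)  # ceil
        m[i, a:b] = 1.0 / (b - a)
    return m


def adaptive_avg_pool2d(x, out_hw):
    oh, ow = _as_pair(out_hw)
    B, C, H, W = x.shape
    if oh > H or ow > W:
        raise ValueError(f"adaptive_avg_pool2d: target {(oh, ow)} exceeds input {(H, W)}")
    mh = pool_matrix(H, oh)
    mw = pool_matrix(W, ow)
    y = anp.tensordot(x, mh, axes=([2], [1]))  # (B,C,W,oh)
    y = anp.tensordot(y, mw, axes=([2], [1]))  # (B,C,oh,ow)
    _count(B * C * (oh * W + oh * ow) * 2)
    return y


# ---------------------------------------------------------------------------
# resampling


def _nearest_matrix(in_size: int, out_size: int) -> np.ndarray:
    idx = np.minimum((np.arange(out_size) * in_size) // out_size, in_size - 1)
    m = np.zeros((out_size, in_size))
    m[np.arange(out_size), idx] = 1.0
    return m


def _bilinear_matrix(in_size: int, out_size: int) -> np.ndarray:
    # half-pixel-center source coordinates (align_corners = false)
    m = np.zeros((out_size, in_size))
    src = (np.arange(out_size) + 0.5) * in_size / out_size - 0.5
    src = np.clip(src, 0, in_size - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, in_size - 1)
    frac = src - lo
    m[np.arange(out_size), lo] += 1.0 - frac
    m[np.arange(out_size), hi] += frac
    return m


def interpolate(x, out_hw, mode="nearest"):
    """Resample the two trailing axes to ``out_hw`` (nearest or bilinear,
    half-pixel convention)."""
    oh, ow = _as_pair(out_hw)
    B, C, H, W = x.shape
    build = _nearest_matrix if mode == "nearest" else _bilinear_matrix
    mh, mw = build(H, oh), build(W, ow)
    y = anp.tensordot(x, mh, axes=([2], [1]))
    y = anp.tensordot(y, mw, axes=([2], [1]))
    _count(2 * B * C * (oh * W + oh * ow) * (1 if mode == "nearest" else 2))
    return y


# ---------------------------------------------------------------------------
# window unfolding (stride-1, same padding)


def unfold_windows(x, k: int):
    """Return overlapping k x k windows of ``x`` as (B, C, k*k, H*W).

    Windows are centred on every spatial position (zero padding k//2), so
    the slot index k*k//2 is the window's own position.
    """
    if k % 2 == 0:
        raise ValueError("unfold_windows requires odd k")
    B, C, H, W = x.shape
    p = k // 2
    xp = anp.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), "constant")
    slots = []
    for i in range(k):
        for j in range(k):
            slots.append(xp[:, :, i : i + H, j : j + W])
    y = anp.stack(slots, axis=2)  # (B,C,k*k,H,W)
    return anp.reshape(y, (B, C, k * k, H * W))


def matmul_count(*shape_terms):
    """Report 2xMAC cost of an attention-style contraction to the counter."""
    n = 2
    for s in shape_terms:
        n *= s
    _count(n)
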