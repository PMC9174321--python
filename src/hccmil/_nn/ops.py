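"""Differentiable operations for the NumPy NN engine.

Convolutions use a shift-and-add scheme: one BLAS tensordot per kernel
offset, which is fast at the small spatial sizes used here and has an
exactly symmetric backward pass.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _accumulate, make


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return make(out_data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    out_data = a.data * c

    def backward(g):
        _accumulate(a, g * c)

    return make(out_data, (a,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0).astype(np.float32)

    def backward(g):
        _accumulate(x, g * mask)

    return make(out_data, (x,), backward)


def relu6(x: Tensor) -> Tensor:
    out_data = np.clip(x.data, 0.0, 6.0)
    mask = (x.data > 0) & (x.data < 6)

    def backward(g):
        _accumulate(x, g * mask)

    return make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))

    def backward(g):
        _accumulate(x, g * out_data * (1.0 - out_data))

    return make(out_data.astype(np.float32), (x,), backward)


def mean(x: Tensor) -> Tensor:
    n = x.data.size
    out_data = np.asarray(x.data.mean(), dtype=np.float32)

    def backward(g):
        _accumulate(x, np.full_like(x.data, float(g) / n))

    return make(out_data, (x,), backward)


def sum_all(x: Tensor) -> Tensor:
    out_data = np.asarray(x.data.sum(), dtype=np.float32)

    def backward(g):
        _accumulate(x, np.full_like(x.data, float(g)))

    return make(out_data, (x,), backward)


def reshape(x: Tensor, shape: tuple) -> Tensor:
    orig = x.data.shape
    out_data = x.data.reshape(shape)

    def backward(g):
        _accumulate(x, g.reshape(orig))

    return make(out_data, (x,), backward)


def concat_features(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along axis 1 of (N, F) tensors."""
    fa = a.data.shape[1]
    out_data = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        _accumulate(a, g[:, :fa])
        _accumulate(b, g[:, fa:])

    return make(out_data, (a, b), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along axis 1 (channels) of NCHW tensors."""
    ca = a.data.shape[1]
    out_data = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        _accumulate(a, g[:, :ca])
        _accumulate(b, g[:, ca:])

    return make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x: (N, F), w: (F, O), b: (O,) -> (N, O)."""
    out_data = x.data @ w.data
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        _accumulate(x, g @ w.data.T)
        _accumulate(w, x.data.T @ g)
        if b is not None:
            _accumulate(b, g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return make(out_data, parents, backward)


# ---------------------------------------------------------------------------
# convolution / pooling / upsampling
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, depthwise: bool = False) -> Tensor:
    """2-D convolution on NCHW input.

    ``w`` has shape (OC, C, kh, kw), or (C, 1, kh, kw) when ``depthwise``.
    Only ``groups in {1, C}`` topologies are supported, which covers the
    dense and depthwise-separable blocks used by the networks here.
    """
    N, C, H, W = x.data.shape
    kh, kw = w.data.shape[2], w.data.shape[3]
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    OC = C if depthwise else w.data.shape[0]
    out_data = np.zeros((N, OC, OH, OW), dtype=np.float32)

    def patch(arr, i, j):
        return arr[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride]

    if depthwise:
        for i in range(kh):
            for j in range(kw):
                out_data += w.data[:, 0, i, j][None, :, None, None] * patch(xp, i, j)
    else:
        for i in range(kh):
            for j in range(kw):
                # (N,C,OH,OW) x (OC,C) -> (N,OH,OW,OC)
                t = np.tensordot(patch(xp, i, j), w.data[:, :, i, j], axes=([1], [1]))
                out_data += t.transpose(0, 3, 1, 2)
    if b is not None:
        out_data += b.data[None, :, None, None]

    def backward(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                pij = patch(xp, i, j)
                if depthwise:
                    gw[:, 0, i, j] = (g * pij).sum(axis=(0, 2, 3))
                    patch(gxp, i, j)[...] += g * w.data[:, 0, i, j][None, :, None, None]
                else:
                    gw[:, :, i, j] = np.tensordot(g, pij, axes=([0, 2, 3], [0, 2, 3]))
                    t = np.tensordot(g, w.data[:, :, i, j], axes=([1], [0]))
                    patch(gxp, i, j)[...] += t.transpose(0, 3, 1, 2)
        _accumulate(w, gw)
        if padding:
            _accumulate(x, gxp[:, :, padding:padding + H, padding:padding + W])
        else:
            _accumulate(x, gxp)
        if b is not None:
            _accumulate(b, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return make(out_data, parents, backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    r = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(N, C, H // 2, W // 2, 4)
    idx = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((N, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        _accumulate(x, gx.reshape(N, C, H, W))

    return make(out_data, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    N, C, H, W = x.data.shape

    def backward(g):
        gx = g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5))
        _accumulate(x, gx)

    return make(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> (N, C) spatial mean."""
    N, C, H, W = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        _accumulate(x, np.broadcast_to(g[:, :, None, None] / (H * W), x.data.shape))

    return make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# bag-level scalar operations
# ---------------------------------------------------------------------------

def signed_power_sum(s: Tensor, p: float) -> Tensor:
    """T = sum_i sign(s_i) |s_i|^p  (equals sum s_i^p for odd integer p)."""
    a = np.abs(s.data)
    out_data = np.asarray((np.sign(s.data) * a ** p).sum(), dtype=np.float32)

    def backward(g):
        _accumulate(s, float(g) * p * a ** (p - 1.0))

    return make(out_data, (s,), backward)


def signed_root(t: Tensor, p: float, tiny: float = 1e-8) -> Tensor:
    """S = sign(t) |t|^(1/p), with the gradient clamped near t = 0."""
    a = float(np.abs(t.data))
    out_data = np.asarray(np.sign(t.data) * a ** (1.0 / p), dtype=np.float32)

    def backward(g):
        _accumulate(t, np.asarray(float(g) / p * max(a, tiny) ** (1.0 / p - 1.0),
                                  dtype=np.float32))

    return make(out_data, (t,), backward)


def prob_transform_op(a: Tensor, t: float) -> Tensor:
    """Piecewise-linear map of the activated bag score to a probability.

    a <= t: p = ((t - a)/t + 1) * 0.5 ; a > t: p = (1 - (a - t)/(1 - t)) * 0.5.
    Continuous and strictly decreasing on [0, 1] with p(t) = 0.5.
    """
    av = float(a.data)
    if av <= t:
        out = ((t - av) / t + 1.0) * 0.5
        slope = -0.5 / t
    else:
        out = (1.0 - (av - t) / (1.0 - t)) * 0.5
        slope = -0.5 / (1.0 - t)

    def backward(g):
        _accumulate(a, np.asarray(float(g) * slope, dtype=np.float32))

    return make(np.asarray(out, dtype=np.float32), (a,), backward)


def binary_cross_entropy(p: Tensor, y: float, delta: float = 1e-7) -> Tensor:
    """-[y log p + (1-y) log(1-p)] with p clipped to [delta, 1-delta]."""
    pc = float(np.clip(p.data, delta, 1.0 - delta))
    out = -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))

    def backward(g):
        grad = (-y / pc + (1.0 - y) / (1.0 - pc)) * float(g)
        # clipped region has zero gradient
        if delta < float(p.data) < 1.0 - delta:
            _accumulate(p, np.asarray(grad, dtype=np.float32))
        else:
            _accumulate(p, np.asarray(0.0, dtype=np.float32))

    return make(np.asarray(out, dtype=np.float32), (p,), backward)
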