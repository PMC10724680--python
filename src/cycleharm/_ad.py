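"""Compact reverse-mode automatic differentiation for 3D convolutional nets.

The networks in this package are small (a handful of strided 3D convolutions)
so the engine stays deliberately minimal: a :class:`Tensor` wrapping a numpy
array plus exactly the operations the generator/discriminator need —
strided 3D convolution, transposed convolution, leaky rectifier, channel
concatenation, instance normalization with mean-absolute-deviation scaling,
and the elementwise/reduction ops used by the losses.  Convolutions are
implemented as im2col/col2im around single BLAS matmuls; forward transposed
convolution, convolution input-gradient and weight-gradient are the three
adjoint faces of one primitive and share code.

An optional storage policy keeps intermediate activations in float16 while
all arithmetic runs in float32 (reduced-precision activation storage); it is
off by default.

All gradients are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

from itertools import product
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Adam", "set_storage_dtype", "conv3d", "conv_transpose3d",
           "leaky_relu", "clamp_min", "mad_instance_norm", "concat_channels",
           "add", "sub", "mul", "scale", "abs_", "square", "mean_", "add_scalar"]

_COMPUTE = np.float32
_STORAGE = np.float32


def set_storage_dtype(dtype) -> None:
    """Set the dtype used to *store* activations (compute stays float32)."""
    global _STORAGE
    _STORAGE = np.dtype(dtype)


def _store(a: np.ndarray) -> np.ndarray:
    return a if a.dtype == _STORAGE else a.astype(_STORAGE)


class Tensor:
    """A numpy array with a backward closure for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (), backward: Callable | None = None):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        g = g.astype(np.float32) if g.dtype != np.float32 else g
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data, dtype=np.float32)
        self.accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=_COMPUTE))


# ---------------------------------------------------------------------------
# convolution primitives (raw arrays)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    """Return (cols, out_spatial): cols has shape (N*P, C*k^3)."""
    n, c = x.shape[:2]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]
    do, dh, dw = win.shape[2:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * do * dh * dw, c * k ** 3)
    return np.ascontiguousarray(cols, dtype=_COMPUTE), (do, dh, dw)


def _conv_fwd(x: np.ndarray, w: np.ndarray, stride: int, pad: int,
              return_cols: bool = False):
    """y[n,o] = sum_c x[n,c] * w[o,c]  (cross-correlation, stride, zero pad)."""
    n = x.shape[0]
    o, _, k = w.shape[:3]
    cols, (do, dh, dw) = _im2col(x, k, stride, pad)
    y = cols @ w.reshape(o, -1).T.astype(_COMPUTE)
    y = y.reshape(n, do, dh, dw, o).transpose(0, 4, 1, 2, 3)
    return (y, cols) if return_cols else y


def _conv_dx(gy: np.ndarray, w: np.ndarray, stride: int, pad: int,
             in_spatial: tuple[int, int, int]) -> np.ndarray:
    """Adjoint of _conv_fwd w.r.t. x.  gy: (N,O,do,dh,dw); returns (N,C,*in_spatial)."""
    n, o, do, dh, dw = gy.shape
    c, k = w.shape[1], w.shape[2]
    g2 = gy.transpose(0, 2, 3, 4, 1).reshape(-1, o).astype(_COMPUTE)
    gcols = g2 @ w.reshape(o, -1).astype(_COMPUTE)          # (N*P, C*k^3)
    # scatter-add (col2im): one strided add per kernel offset, reading the
    # GEMM output through a transposed view to avoid a full-size copy
    gcols = gcols.reshape(n, do, dh, dw, c, k, k, k).transpose(0, 4, 5, 6, 7, 1, 2, 3)
    ps = [s + 2 * pad for s in in_spatial]
    gxp = np.zeros((n, c, *ps), dtype=_COMPUTE)
    for i, j, l in product(range(k), range(k), range(k)):
        gxp[:, :, i:i + do * stride:stride,
            j:j + dh * stride:stride,
            l:l + dw * stride:stride] += gcols[:, :, i, j, l]
    if pad:
        gxp = gxp[:, :, pad:-pad, pad:-pad, pad:-pad]
    return gxp


def _conv_dw(x: np.ndarray, gy: np.ndarray, k: int, stride: int, pad: int,
             cols: np.ndarray | None = None) -> np.ndarray:
    """Adjoint of _conv_fwd w.r.t. w.  Returns (O,C,k,k,k).  ``cols`` may be
    the cached im2col matrix from the forward pass."""
    n, o = gy.shape[0], gy.shape[1]
    c = x.shape[1]
    if cols is None:
        cols, _ = _im2col(x, k, stride, pad)
    g2 = gy.transpose(0, 2, 3, 4, 1).reshape(-1, o).astype(_COMPUTE)
    return (g2.T @ cols).reshape(o, c, k, k, k)


def transpose_conv_out_shape(in_spatial: Sequence[int], k: int, stride: int,
                             pad: int) -> tuple[int, ...]:
    return tuple((s - 1) * stride - 2 * pad + k for s in in_spatial)


# ---------------------------------------------------------------------------
# autodiff ops
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2, pad: int = 1) -> Tensor:
    """Strided 3D convolution.  x: (N,C,D,H,W); w: (O,C,k,k,k); b: (O,)."""
    xd = x.data
    y, cols = _conv_fwd(xd, w.data, stride, pad, return_cols=True)
    y += b.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(_store(y), parents=(x, w, b))
    k = w.data.shape[2]
    in_spatial = xd.shape[2:]
    cache = cols if w.requires_grad else None

    def backward(g):
        if x.requires_grad:
            x.accumulate(_conv_dx(g, w.data, stride, pad, in_spatial))
        if w.requires_grad:
            w.accumulate(_conv_dw(xd, g, k, stride, pad, cols=cache))
        if b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3, 4)))
    out._backward = backward
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2, pad: int = 1) -> Tensor:
    """Transposed 3D convolution (adjoint of conv3d).  w: (I,O,k,k,k)."""
    xd = x.data
    k = w.data.shape[2]
    out_spatial = transpose_conv_out_shape(xd.shape[2:], k, stride, pad)
    y = _conv_dx(xd.astype(_COMPUTE), w.data, stride, pad, out_spatial)
    y = y + b.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(_store(y), parents=(x, w, b))

    def backward(g):
        if x.requires_grad:
            x.accumulate(_conv_fwd(g, w.data, stride, pad))
        if w.requires_grad:
            w.accumulate(_conv_dw(g, xd.astype(_COMPUTE), k, stride, pad))
        if b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3, 4)))
    out._backward = backward
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    pos = x.data > 0
    y = np.where(pos, x.data, slope * x.data)
    out = Tensor(_store(y), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x.accumulate(np.where(pos, g, np.float32(slope) * g))
    out._backward = backward
    return out


def clamp_min(x: Tensor, lo: float = 0.0) -> Tensor:
    """Identity above ``lo``, clamped below — the generator's final activation."""
    keep = x.data > lo
    out = Tensor(_store(np.where(keep, x.data, lo)), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x.accumulate(np.where(keep, g, 0.0).astype(np.float32))
    out._backward = backward
    return out


def mad_instance_norm(x: Tensor, gain: Tensor, offset: Tensor, eps: float = 1e-5,
                      rescale: bool = False) -> Tensor:
    """Instance normalization with the standard deviation replaced by the
    mean absolute deviation: y = (x - mean) / (mad + eps) * gain + offset,
    statistics per channel per instance over the spatial axes.

    If ``rescale`` the MAD is multiplied by sqrt(pi/2), which would make it an
    unbiased SD estimate under Gaussian activations (off by default: the
    deviation replaces the SD, it does not approximate it).
    """
    xd = x.data.astype(_COMPUTE)
    ax = (2, 3, 4)
    nv = float(np.prod(xd.shape[2:]))
    mu = xd.mean(axis=ax, keepdims=True)
    u = xd - mu
    mad = np.abs(u).mean(axis=ax, keepdims=True)
    if rescale:
        mad = mad * np.float32(np.sqrt(np.pi / 2.0))
    d = mad + np.float32(eps)
    z = u / d
    gd = gain.data.reshape(1, -1, 1, 1, 1)
    od = offset.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(_store(z * gd + od), parents=(x, gain, offset))
    rs = np.float32(np.sqrt(np.pi / 2.0)) if rescale else np.float32(1.0)

    def backward(g):
        if gain.requires_grad:
            gain.accumulate((g * z).sum(axis=(0, 2, 3, 4)))
        if offset.requires_grad:
            offset.accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gz = g * gd
            # through u directly, through mad, then through mean
            s = (gz * u).sum(axis=ax, keepdims=True)
            gu = gz / d - (s / (d * d)) * (np.sign(u) * rs / np.float32(nv))
            gx = gu - gu.mean(axis=ax, keepdims=True)
            x.accumulate(gx.astype(np.float32))
    out._backward = backward
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = Tensor(_store(np.concatenate([a.data, b.data], axis=1)), parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a.accumulate(g[:, :ca])
        if b.requires_grad:
            b.accumulate(g[:, ca:])
    out._backward = backward
    return out


def _binary(a: Tensor, b: Tensor, y, da, db) -> Tensor:
    out = Tensor(_store(y), parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(da(g), a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(db(g), b.data.shape))
    out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def sub(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data - b.data, lambda g: g, lambda g: -g)


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data * b.data,
                   lambda g: g * b.data, lambda g: g * a.data)


def scale(x: Tensor, c: float) -> Tensor:
    out = Tensor(_store(x.data * np.float32(c)), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * np.float32(c))
    out._backward = backward
    return out


def add_scalar(x: Tensor, c: float) -> Tensor:
    out = Tensor(_store(x.data + np.float32(c)), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x.accumulate(g)
    out._backward = backward
    return out


def abs_(x: Tensor) -> Tensor:
    sgn = np.sign(x.data)
    out = Tensor(_store(np.abs(x.data)), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * sgn)
    out._backward = backward
    return out


def square(x: Tensor) -> Tensor:
    out = Tensor(_store(x.data * x.data), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * (2.0 * x.data).astype(np.float32))
    out._backward = backward
    return out


def mean_(x: Tensor) -> Tensor:
    n = float(x.data.size)
    out = Tensor(np.float32(x.data.mean()), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x.accumulate(np.full(x.data.shape, float(g) / n, dtype=np.float32))
    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with bias correction; operates on a list of parameter Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data = p.data - self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
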