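"""Minimal reverse-mode automatic differentiation on numpy arrays.

A define-by-run tape: every operation returns a new :class:`Tensor` holding the
result and a closure that propagates the upstream gradient to its parents.
Only the operations the segmentation network needs are implemented, each with
an analytically derived backward pass (verified against central finite
differences in the test suite).

All computation is plain single-threaded numpy, so forward passes are bitwise
reproducible for identical inputs and parameters.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "log",
    "clip",
    "concat",
    "narrow",
    "reshape",
    "sum_",
    "mean_",
    "softmax",
    "conv2d",
    "depthwise_conv2d",
    "avg_pool2d",
    "max_pool2d",
    "bilinear_resize",
    "global_avg_pool",
    "attention_pool",
    "batch_norm2d",
    "layer_norm",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- convenience -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(np.asarray(-1.0, dtype=self.dtype)))

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return mul(self, reciprocal(as_tensor(other)))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), reciprocal(self))

    # -- autodiff --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of this (scalar, unless ``grad`` given) output
        into every reachable parent with ``requires_grad``."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _needs_grad(*parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def reciprocal(a: Tensor) -> Tensor:
    data = 1.0 / a.data

    def backward(g):
        a._accumulate(-g * data * data)

    return _make(data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _make(data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        a._accumulate(g * mask)

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable two-sided formulation
    x = a.data
    data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                    np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

    def backward(g):
        a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def log(a: Tensor) -> Tensor:
    data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; the gradient is passed through inside [lo, hi] only."""
    data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        a._accumulate(g * mask)

    return _make(data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _make(data, tuple(tensors), backward)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Slice ``length`` entries from ``start`` along ``axis``."""
    index = [slice(None)] * a.data.ndim
    index[axis] = slice(start, start + length)
    index = tuple(index)
    data = a.data[index]

    def backward(g):
        full = np.zeros_like(a.data)
        full[index] = g
        a._accumulate(full)

    return _make(data, (a,), backward)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), backward)


def mean_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    elif isinstance(axis, tuple):
        n = int(np.prod([a.data.shape[i] for i in axis]))
    else:
        n = a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims),
               Tensor(np.asarray(1.0 / n, dtype=a.dtype)))


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        a._accumulate(data * (g - dot))

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# convolution machinery
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int, dilation: int) -> np.ndarray:
    """Return sliding windows of shape (N, C, Ho, Wo, k, k) for stride-1
    correlation with the given zero padding and kernel dilation."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    keff = dilation * (k - 1) + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (keff, keff), axis=(2, 3))
    if dilation > 1:
        win = win[..., ::dilation, ::dilation]
    return win


def _corr2d(x: np.ndarray, w: np.ndarray, pad: int, dilation: int) -> np.ndarray:
    """Dense stride-1 cross-correlation. w: (Cout, Cin, k, k)."""
    k = w.shape[-1]
    col = _im2col(x, k, pad, dilation)
    n, c, ho, wo = col.shape[:4]
    cols = np.ascontiguousarray(col.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, c * k * k)
    out = cols @ w.reshape(w.shape[0], -1).T
    return out.reshape(n, ho, wo, w.shape[0]).transpose(0, 3, 1, 2)


def _conv2d_1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise convolution as a batched GEMM (the hot path of the network)."""
    n, c, h, wd = x.data.shape
    w2 = w.data.reshape(w.data.shape[0], c)
    out = np.matmul(w2, x.data.reshape(n, c, h * wd))
    data = out.reshape(n, w2.shape[0], h, wd)
    if b is not None:
        data = data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2 = g.reshape(n, w2.shape[0], h * wd)
        x2 = x.data.reshape(n, c, h * wd)
        dw = np.matmul(g2, x2.transpose(0, 2, 1)).sum(axis=0)
        w._accumulate(dw.reshape(w.data.shape))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        dx = np.matmul(w2.T, g2).reshape(n, c, h, wd)
        x._accumulate(dx)

    return _make(data, parents, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, pad: int = 0, dilation: int = 1) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) with zero padding.

    x: (N, Cin, H, W); w: (Cout, Cin, k, k); b: (Cout,) or None.
    """
    k = w.data.shape[-1]
    if k == 1 and pad == 0:
        return _conv2d_1x1(x, w, b)
    data = _corr2d(x.data, w.data, pad, dilation)
    if b is not None:
        data = data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        # dW: correlate input windows with the upstream gradient
        col = _im2col(x.data, k, pad, dilation)
        dw = np.einsum("nohw,nchwij->ocij", g, col, optimize=True)
        w._accumulate(dw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        # dX: full correlation of g with the flipped kernel, channels swapped
        wflip = np.ascontiguousarray(w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        gpad = dilation * (k - 1) - pad
        dx = _corr2d(g, wflip, gpad, dilation)
        x._accumulate(dx)

    return _make(data, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None, pad: int = 0) -> Tensor:
    """Depthwise stride-1 convolution. w: (C, k, k), one filter per channel."""
    k = w.data.shape[-1]
    col = _im2col(x.data, k, pad, 1)
    data = np.einsum("nchwij,cij->nchw", col, w.data, optimize=True)
    if b is not None:
        data = data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        colb = _im2col(x.data, k, pad, 1)
        w._accumulate(np.einsum("nchw,nchwij->cij", g, colb, optimize=True))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        wflip = np.ascontiguousarray(w.data[:, ::-1, ::-1])
        gcol = _im2col(g, k, k - 1 - pad, 1)
        x._accumulate(np.einsum("nchwij,cij->nchw", gcol, wflip, optimize=True))

    return _make(data, parents, backward)


# ---------------------------------------------------------------------------
# pooling and resampling
# ---------------------------------------------------------------------------

def avg_pool2d(x: Tensor, k: int) -> Tensor:
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h}, {w}) not divisible by pool size {k}")
    data = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(g):
        gx = np.broadcast_to(g[:, :, :, None, :, None] / (k * k),
                             (n, c, h // k, k, w // k, k))
        x._accumulate(gx.reshape(n, c, h, w).copy())

    return _make(data, (x,), backward)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h}, {w}) not divisible by pool size {k}")
    blocks = x.data.reshape(n, c, h // k, k, w // k, k)
    data = blocks.max(axis=(3, 5))
    # ties share the gradient equally, keeping backward deterministic
    mask = (blocks == data[:, :, :, None, :, None])
    counts = mask.sum(axis=(3, 5), keepdims=True)

    def backward(g):
        gx = mask * (g[:, :, :, None, :, None] / counts)
        x._accumulate(gx.reshape(n, c, h, w))

    return _make(data, (x,), backward)


@lru_cache(maxsize=128)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (n_out, n_in), half-pixel centers."""
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = src - lo
    m[np.arange(n_out), lo] += 1.0 - t
    m[np.arange(n_out), hi] += t
    return m


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resampling to (out_h, out_w), half-pixel (align_corners=False)
    convention, expressed as two separable interpolation matrices."""
    n, c, h, w = x.data.shape
    ah = _interp_matrix(h, out_h).astype(x.dtype)
    aw = _interp_matrix(w, out_w).astype(x.dtype)
    data = np.einsum("ph,qw,nchw->ncpq", ah, aw, x.data, optimize=True)

    def backward(g):
        x._accumulate(np.einsum("ph,qw,ncpq->nchw", ah, aw, g, optimize=True))

    return _make(data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) per-channel spatial mean."""
    n, c, h, w = x.data.shape
    data = x.data.mean(axis=(2, 3))

    def backward(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).copy())

    return _make(data, (x,), backward)


def attention_pool(x: Tensor, beta: Tensor) -> Tensor:
    """Global attention pooling: sum over positions of beta-weighted features.

    x: (N, C, H, W); beta: (N, 1, H, W) position weights -> (N, C).
    """
    data = np.einsum("nchw,nqhw->nc", x.data, beta.data, optimize=True)

    def backward(g):
        x._accumulate(g[:, :, None, None] * beta.data)
        beta._accumulate(np.einsum("nchw,nc->nhw", x.data, g,
                                   optimize=True)[:, None, :, :])

    return _make(data, (x, beta), backward)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 mean: np.ndarray, var: np.ndarray, eps: float,
                 use_batch_stats: bool) -> Tensor:
    """Channelwise batch normalization.

    In training (``use_batch_stats``) the statistics of the current batch are
    used and gradients flow through them; in inference the supplied running
    ``mean``/``var`` are constants.
    """
    if use_batch_stats:
        mu = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
    else:
        mu, v = mean, var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        gi = g * gamma.data[None, :, None, None]
        if use_batch_stats:
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            mean_gi = gi.mean(axis=(0, 2, 3))
            mean_gx = (gi * xhat).mean(axis=(0, 2, 3))
            dx = inv[None, :, None, None] * (
                gi - mean_gi[None, :, None, None] - xhat * mean_gx[None, :, None, None])
            x._accumulate(dx)
        else:
            x._accumulate(gi * inv[None, :, None, None])

    return _make(data, (x, gamma, beta), backward), mu, v


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis of a (N, C) tensor."""
    mu = x.data.mean(axis=-1, keepdims=True)
    v = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - mu) * inv
    data = gamma.data * xhat + beta.data

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=0))
        beta._accumulate(g.sum(axis=0))
        gi = g * gamma.data
        c = x.data.shape[-1]
        dx = inv * (gi - gi.mean(axis=-1, keepdims=True)
                    - xhat * (gi * xhat).mean(axis=-1, keepdims=True))
        x._accumulate(dx)

    return _make(data, (x, gamma, beta), backward)
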