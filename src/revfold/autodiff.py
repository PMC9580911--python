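"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training objective differentiates through 1D convolutions, dynamically
rebuilt graph Laplacians, instance normalization, the Verlet recursion, the
chain-length constraint and the distance-matrix loss.  This module provides a
small tape-based engine with exactly the primitives those computations need.
Gradients are verified against central finite differences in the test suite.

Conventions: feature maps are (channels, positions) matrices; convolution
kernels are (out_channels, in_channels, taps) with zero same-padding.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "astensor", "add", "sub", "mul", "div", "neg", "matmul",
    "transpose", "exp", "log", "relu", "absolute", "safe_sqrt", "tsum",
    "tmean", "square", "conv1d", "diag_embed", "slice_cols", "concat_cols",
    "cumsum_cols", "scale",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    # operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    @property
    def T(self):
        return transpose(self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def item(self):
        return float(self.data)

    # backward pass ------------------------------------------------------
    def backward(self, seed=None):
        """Accumulate gradients of this (scalar) tensor into the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if seed is None else np.asarray(seed, float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def astensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=False)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad and t._backward is None:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# primitives -------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def sub(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data - b.data, (a, b))

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    out._backward = bw
    return out


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data * b.data, (a, b))

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data / b.data, (a, b))

    def bw(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / b.data**2, b.data.shape))

    out._backward = bw
    return out


def neg(a) -> Tensor:
    a = astensor(a)
    out = Tensor(-a.data, (a,))
    out._backward = lambda g: _accum(a, -g)
    return out


def scale(a, s: float) -> Tensor:
    """Multiply by a python scalar (cheaper than a broadcast mul node)."""
    a = astensor(a)
    out = Tensor(a.data * s, (a,))
    out._backward = lambda g: _accum(a, g * s)
    return out


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = Tensor(a.data @ b.data, (a, b))

    def bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    out._backward = bw
    return out


def transpose(a) -> Tensor:
    a = astensor(a)
    out = Tensor(a.data.T, (a,))
    out._backward = lambda g: _accum(a, g.T)
    return out


def exp(a) -> Tensor:
    a = astensor(a)
    out = Tensor(np.exp(a.data), (a,))
    out._backward = lambda g: _accum(a, g * out.data)
    return out


def log(a) -> Tensor:
    a = astensor(a)
    out = Tensor(np.log(a.data), (a,))
    out._backward = lambda g: _accum(a, g / a.data)
    return out


def relu(a) -> Tensor:
    a = astensor(a)
    out = Tensor(np.maximum(a.data, 0.0), (a,))
    out._backward = lambda g: _accum(a, g * (a.data > 0))
    return out


def absolute(a) -> Tensor:
    a = astensor(a)
    out = Tensor(np.abs(a.data), (a,))
    out._backward = lambda g: _accum(a, g * np.sign(a.data))
    return out


def square(a) -> Tensor:
    a = astensor(a)
    out = Tensor(a.data * a.data, (a,))
    out._backward = lambda g: _accum(a, 2.0 * g * a.data)
    return out


def safe_sqrt(a, eps: float = 1e-12) -> Tensor:
    """sqrt(max(a, 0)) whose gradient is zeroed where a <= eps.

    Pairwise self-distances sit at (numerical) zero where the true sqrt
    gradient is unbounded; those entries never carry useful signal, so their
    gradient is defined as 0.
    """
    a = astensor(a)
    clamped = np.maximum(a.data, 0.0)
    out = Tensor(np.sqrt(clamped), (a,))

    def bw(g):
        safe = a.data > eps
        grad = np.zeros_like(a.data)
        grad[safe] = 0.5 * g[safe] / out.data[safe]
        _accum(a, grad)

    out._backward = bw
    return out


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def bw(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(g, a.data.shape).copy())

    out._backward = bw
    return out


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    count = a.data.size if axis is None else a.data.shape[axis]
    return scale(tsum(a, axis=axis, keepdims=keepdims), 1.0 / count)


def diag_embed(v) -> Tensor:
    """Vector (n,) -> diagonal matrix (n, n)."""
    v = astensor(v)
    out = Tensor(np.diag(v.data), (v,))
    out._backward = lambda g: _accum(v, np.diagonal(g).copy())
    return out


def slice_cols(a, start, stop) -> Tensor:
    a = astensor(a)
    out = Tensor(a.data[:, start:stop], (a,))

    def bw(g):
        full = np.zeros_like(a.data)
        full[:, start:stop] = g
        _accum(a, full)

    out._backward = bw
    return out


def concat_cols(parts) -> Tensor:
    parts = [astensor(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts], axis=1), tuple(parts))
    widths = [p.data.shape[1] for p in parts]

    def bw(g):
        off = 0
        for p, w in zip(parts, widths):
            _accum(p, g[:, off:off + w])
            off += w

    out._backward = bw
    return out


def cumsum_cols(a) -> Tensor:
    a = astensor(a)
    out = Tensor(np.cumsum(a.data, axis=1), (a,))
    # adjoint of cumsum is reversed cumsum
    out._backward = lambda g: _accum(a, np.cumsum(g[:, ::-1], axis=1)[:, ::-1])
    return out


def _conv1d_raw(K: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Correlation with zero same-padding: out[o,p] = sum_{i,t} K[o,i,t] Y[i,p+t-pad]."""
    k = K.shape[2]
    pad = k // 2
    Ypad = np.pad(Y, ((0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(Ypad, k, axis=1)
    # out[o,p] = sum_{i,t} K[o,i,t] win[i,p,t]
    return np.tensordot(K, win, axes=([1, 2], [0, 2]))


def conv1d(K, Y, adjoint: bool = False) -> Tensor:
    """1D convolution along the chain, zero same-padding, stride 1.

    With ``adjoint=True`` applies the exact adjoint operator (transposed
    channels, flipped taps) using the same kernel storage, so that
    ``<conv(K,Y), Z> == <Y, conv(K,Z,adjoint=True)>``.
    """
    K, Y = astensor(K), astensor(Y)
    Kap = K.data.transpose(1, 0, 2)[:, :, ::-1] if adjoint else K.data
    out = Tensor(_conv1d_raw(Kap, Y.data), (K, Y))
    k = K.data.shape[2]
    pad = k // 2

    def bw(g):
        # gradient w.r.t. Y: adjoint of the applied operator
        Kadj = Kap.transpose(1, 0, 2)[:, :, ::-1]
        _accum(Y, _conv1d_raw(Kadj, g))
        # gradient w.r.t. the applied kernel
        Ypad = np.pad(Y.data, ((0, 0), (pad, pad)))
        win = np.lib.stride_tricks.sliding_window_view(Ypad, k, axis=1)
        # gK[o,i,t] = sum_p g[o,p] win[i,p,t]
        gK_ap = np.tensordot(g, win, axes=([1], [1]))
        if adjoint:
            gK_ap = gK_ap.transpose(1, 0, 2)[:, :, ::-1]
        _accum(K, np.ascontiguousarray(gK_ap))

    out._backward = bw
    return out
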