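"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network code in :mod:`apanet.network` only needs a small set of
primitives (batched matmul against 2-D weight matrices, elementwise
arithmetic, relu/tanh/sigmoid, 1-D max pooling, slicing, concatenation,
log-softmax and reductions), so the engine implements exactly those.
Gradients are only propagated into tensors that require them; wrapping a
forward pass in :class:`no_grad` skips graph construction entirely.

All data is float64. Gradient correctness is verified against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = []  # list of (Tensor, grad_fn)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph ---------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t.grad is None:
                continue
            for p, gfn in t._parents:
                g = gfn(t.grad)
                if p.grad is None:
                    p.grad = g.copy()
                else:
                    p.grad += g

    # -- operator sugar ------------------------------------------------

    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __neg__(self):
        return mul_const(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(-self, _as_tensor(other))

    def __mul__(self, other):
        if np.isscalar(other):
            return mul_const(self, other)
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, idx):
        return getitem(self, idx)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _result(data, parents) -> Tensor:
    """Build an op result; record parents only when grads are live."""
    track = _GRAD_ENABLED and any(p.requires_grad for p, _ in parents)
    out = Tensor(data, requires_grad=track)
    if track:
        out._parents = [(p, g) for p, g in parents if p.requires_grad]
    return out


# -- primitives --------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    return _result(
        a.data + b.data,
        [(a, lambda g: _unbroadcast(g, a.data.shape)),
         (b, lambda g: _unbroadcast(g, b.data.shape))],
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _result(
        a.data * b.data,
        [(a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
         (b, lambda g: _unbroadcast(g * a.data, b.data.shape))],
    )


def mul_const(a: Tensor, c: float) -> Tensor:
    return _result(a.data * c, [(a, lambda g: g * c)])


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """`a @ b` where b is a 2-D weight matrix; a may carry leading batch dims."""
    if b.data.ndim != 2:
        raise ValueError("matmul: right operand must be 2-D")
    out = a.data @ b.data

    def ga(g):
        return g @ b.data.T

    def gb(g):
        k = a.data.shape[-1]
        return a.data.reshape(-1, k).T @ g.reshape(-1, b.data.shape[1])

    return _result(out, [(a, ga), (b, gb)])


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return _result(a.data * mask, [(a, lambda g: g * mask)])


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)
    return _result(y, [(a, lambda g: g * (1.0 - y * y))])


def sigmoid(a: Tensor) -> Tensor:
    y = 0.5 * (np.tanh(0.5 * a.data) + 1.0)  # numerically stable logistic
    return _result(y, [(a, lambda g: g * y * (1.0 - y))])


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    return _result(a.data.reshape(shape), [(a, lambda g: g.reshape(old))])


def getitem(a: Tensor, idx) -> Tensor:
    out = a.data[idx]

    def ga(g):
        gx = np.zeros_like(a.data)
        np.add.at(gx, idx, g)
        return gx

    return _result(out, [(a, ga)])


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    parents = []
    for i, t in enumerate(tensors):
        lo, hi = offsets[i], offsets[i + 1]

        def gfn(g, lo=lo, hi=hi):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            return g[tuple(sl)]

        parents.append((t, gfn))
    return _result(out, parents)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def ga(g):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        g2 = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(g2, a.data.shape).copy()

    return _result(out, [(a, ga)])


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul_const(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def maxpool1d(a: Tensor, width: int, stride: int) -> Tensor:
    """Max pooling over axis 1 of a (B, P, F) tensor.

    Positions beyond the last full window are dropped. Ties resolve to
    the lowest position (numpy argmax convention).
    """
    B, P, F = a.data.shape
    starts = np.arange(0, P - width + 1, stride)
    win = a.data[:, starts[:, None] + np.arange(width), :]  # (B, n, width, F)
    am = win.argmax(axis=2)
    out = np.take_along_axis(win, am[:, :, None, :], axis=2)[:, :, 0, :]
    pos = starts[None, :, None] + am  # absolute source positions

    def ga(g):
        gx = np.zeros_like(a.data)
        b_idx = np.arange(B)[:, None, None]
        f_idx = np.arange(F)[None, None, :]
        np.add.at(gx, (b_idx, pos, f_idx), g)
        return gx

    return _result(out, [(a, ga)])


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    x = a.data
    m = x.max(axis=axis, keepdims=True)
    z = x - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    p = np.exp(out)

    def ga(g):
        return g - p * g.sum(axis=axis, keepdims=True)

    return _result(out, [(a, ga)])


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain-numpy softmax with max subtraction (no graph)."""
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
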