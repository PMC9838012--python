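"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module provides exactly the primitives the model needs: dense and
sparse-constant matrix products, broadcasting elementwise arithmetic, a few
nonlinearities, row gathering, row-wise softmax, dropout, and an Adam
optimizer with L2-coupled weight decay.  Everything is float64 and
single-threaded-deterministic: for a fixed seed the whole training loop is
bit-reproducible.

Gradients propagate through a ``Tensor`` graph built eagerly by the ops
below; ``Tensor.backward()`` runs a topological sweep.  Sparse matrices
(scipy) only ever appear as constants (normalized adjacencies), so ``spmm``
needs no gradient with respect to its first argument.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "matmul",
    "spmm",
    "relu",
    "sigmoid",
    "log",
    "exp",
    "softmax_rows",
    "concat",
    "take_rows",
    "dropout",
    "clamp",
    "glorot",
    "Adam",
]


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        g = np.asarray(g, dtype=np.float64)
        self.grad = g if self.grad is None else self.grad + g

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, constant(-1.0))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return tsum(self, axis=axis, keepdims=keepdims) * constant(1.0 / n)

    @property
    def T(self):
        return transpose(self)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x):
    return Tensor(x, requires_grad=False)


def parameter(x):
    return Tensor(x, requires_grad=True)


def _needs(*ts):
    return any(t.requires_grad or t._parents for t in ts)


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# -- primitives ----------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward) if _needs(a, b) else Tensor(out_data)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward) if _needs(a, b) else Tensor(out_data)


def power(a, p):
    a = _as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return Tensor(out_data, parents=(a,), backward=backward) if _needs(a) else Tensor(out_data)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(g @ b.data.T)
        if b.requires_grad or b._parents:
            b._accumulate(a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=backward) if _needs(a, b) else Tensor(out_data)


def spmm(S, x):
    """Product of a constant scipy sparse matrix with a dense tensor."""
    if not sp.issparse(S):
        raise TypeError("spmm expects a scipy sparse matrix as first argument")
    x = _as_tensor(x)
    S = S.tocsr()
    out_data = np.asarray(S @ x.data)

    def backward(g):
        x._accumulate(np.asarray(S.T @ g))

    return Tensor(out_data, parents=(x,), backward=backward) if _needs(x) else Tensor(out_data)


def transpose(a):
    a = _as_tensor(a)

    def backward(g):
        a._accumulate(g.T)

    return Tensor(a.data.T, parents=(a,), backward=backward) if _needs(a) else Tensor(a.data.T)


def tsum(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return Tensor(out_data, parents=(a,), backward=backward) if _needs(a) else Tensor(out_data)


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return Tensor(a.data * mask, parents=(a,), backward=backward) if _needs(a) else Tensor(a.data * mask)


def sigmoid(a):
    a = _as_tensor(a)
    out_data = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                        np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(a,), backward=backward) if _needs(a) else Tensor(out_data)


def log(a):
    a = _as_tensor(a)

    def backward(g):
        a._accumulate(g / a.data)

    out_data = np.log(a.data)
    return Tensor(out_data, parents=(a,), backward=backward) if _needs(a) else Tensor(out_data)


def exp(a):
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return Tensor(out_data, parents=(a,), backward=backward) if _needs(a) else Tensor(out_data)


def softmax_rows(a):
    """Numerically stable softmax along the last axis."""
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        a._accumulate(p * (g - (g * p).sum(axis=-1, keepdims=True)))

    return Tensor(p, parents=(a,), backward=backward) if _needs(a) else Tensor(p)


def concat(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            if t.requires_grad or t._parents:
                t._accumulate(g[tuple(sl)])

    if _needs(*tensors):
        return Tensor(out_data, parents=tuple(tensors), backward=backward)
    return Tensor(out_data)


def take_rows(a, idx):
    a = _as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    out_data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accumulate(full)

    return Tensor(out_data, parents=(a,), backward=backward) if _needs(a) else Tensor(out_data)


def dropout(a, rate, rng, training=True):
    """Inverted dropout; identity when not training or rate == 0."""
    a = _as_tensor(a)
    if not training or rate <= 0.0:
        return a
    keep = rng.random(a.data.shape) >= rate
    scale = keep / (1.0 - rate)

    def backward(g):
        a._accumulate(g * scale)

    out_data = a.data * scale
    return Tensor(out_data, parents=(a,), backward=backward) if _needs(a) else Tensor(out_data)


def clamp(a, lo, hi):
    """Clamp with straight-through zero gradient outside [lo, hi]."""
    a = _as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    inside = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accumulate(g * inside)

    return Tensor(out_data, parents=(a,), backward=backward) if _needs(a) else Tensor(out_data)


# -- parameters & optimization -------------------------------------------

def glorot(rng, shape):
    """Glorot/Xavier-uniform initialization."""
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-limit, limit, size=shape))


class Adam:
    """Adam with L2-coupled weight decay (gradient += wd * param)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
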