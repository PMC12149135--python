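"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine providing exactly the primitives the Nm-site
network needs: broadcast-aware arithmetic, (batched) matmul, the activation
functions, masked softmax for graph attention, 1-D same-padded convolution
and max-pooling, reductions, reshapes and concatenation, plus an Adam
optimizer. Gradients are checked against finite differences in the test
suite.

Dtype follows the input arrays: float32 for training speed, float64 when
tests need tight finite-difference agreement.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "tensor", "parameter", "add", "sub", "mul", "div", "neg",
    "matmul", "relu", "leaky_relu", "elu", "sigmoid", "log", "clip",
    "tsum", "tmean", "reshape", "swap_last_axes", "concat", "softmax",
    "masked_softmax", "conv1d_same", "maxpool1d", "Adam",
]


class Tensor:
    """A numpy array plus the local backward rule that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self):
        """Run reverse-mode accumulation from this (scalar) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # Sugar used throughout the model code.
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def tensor(x):
    """Wrap an array as a constant (no gradient)."""
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def parameter(x):
    """Wrap an array as a trainable leaf."""
    return Tensor(np.asarray(x), requires_grad=True)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents if req else (),
                  backward=backward if req else None)


# ---------------------------------------------------------------- arithmetic

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _make(out_data, (a, b), backward)


def neg(a):
    a = _as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(-g)

    return _make(-a.data, (a,), backward)


def matmul(a, b):
    """Batched matrix product with numpy broadcasting over leading axes."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


# --------------------------------------------------------------- activations

def relu(a):
    a = _as_tensor(a)
    out_data = np.maximum(a.data, 0)

    def backward(g):
        a._accumulate(g * (a.data > 0))

    return _make(out_data, (a,), backward)


def leaky_relu(a, slope=0.2):
    a = _as_tensor(a)
    pos = a.data > 0
    out_data = np.where(pos, a.data, slope * a.data)

    def backward(g):
        a._accumulate(g * np.where(pos, 1.0, slope).astype(a.data.dtype))

    return _make(out_data, (a,), backward)


def elu(a, alpha=1.0):
    a = _as_tensor(a)
    neg_part = alpha * np.expm1(np.minimum(a.data, 0))
    out_data = np.where(a.data > 0, a.data, neg_part)

    def backward(g):
        a._accumulate(g * np.where(a.data > 0, 1.0, neg_part + alpha))

    return _make(out_data, (a,), backward)


def sigmoid(a):
    a = _as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def log(a):
    a = _as_tensor(a)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def clip(a, lo, hi):
    """Clamp; gradient is passed through only on the interior."""
    a = _as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    interior = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accumulate(g * interior)

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------- reductions

def tsum(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).astype(a.data.dtype))
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accumulate(np.broadcast_to(gg, a.shape).astype(a.data.dtype))

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    elif isinstance(axis, tuple):
        n = int(np.prod([a.shape[ax] for ax in axis]))
    else:
        n = a.shape[axis]
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


# --------------------------------------------------------------------- shape

def reshape(a, shape):
    a = _as_tensor(a)
    old = a.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


def swap_last_axes(a):
    a = _as_tensor(a)

    def backward(g):
        a._accumulate(np.swapaxes(g, -1, -2))

    return _make(np.swapaxes(a.data, -1, -2), (a,), backward)


def concat(tensors, axis=-1):
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(p)

    return _make(out_data, tuple(tensors), backward)


# ------------------------------------------------------------------- softmax

def softmax(a, axis=-1):
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate(out_data * (g - dot))

    return _make(out_data, (a,), backward)


def masked_softmax(a, mask, axis=-1):
    """Softmax restricted to positions where ``mask`` is truthy.

    Masked positions receive exactly zero weight and propagate no gradient;
    every row must contain at least one unmasked entry.
    """
    a = _as_tensor(a)
    m = np.asarray(mask, dtype=bool)
    if not np.broadcast_to(m, a.shape).any(axis=axis).all():
        raise ValueError("masked_softmax: a row has an empty neighborhood")
    big_neg = np.finfo(a.data.dtype).min / 4
    z = np.where(m, a.data, big_neg)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z) * m
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate(out_data * (g - dot))

    return _make(out_data, (a,), backward)


# ------------------------------------------------------- conv / pool kernels

def conv1d_same(x, w, b):
    """1-D convolution along axis 1 with zero same-padding.

    x: (B, L, C); w: (k, C, K); b: (K,). Output (B, L, K).
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    B, L, C = x.shape
    k, Cw, K = w.shape
    if Cw != C:
        raise ValueError(f"conv1d_same: input has {C} channels, kernel expects {Cw}")
    pad = k // 2
    xp = np.zeros((B, L + 2 * pad, C), dtype=x.data.dtype)
    xp[:, pad:pad + L] = x.data
    cols = np.concatenate([xp[:, i:i + L] for i in range(k)], axis=2)  # (B, L, k*C)
    w2 = w.data.reshape(k * C, K)
    out_data = cols @ w2 + b.data

    def backward(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = cols.reshape(-1, k * C).T @ g.reshape(-1, K)
            w._accumulate(gw.reshape(k, C, K))
        if x.requires_grad:
            gcols = g @ w2.T  # (B, L, k*C)
            gxp = np.zeros_like(xp)
            for i in range(k):
                gxp[:, i:i + L] += gcols[:, :, i * C:(i + 1) * C]
            x._accumulate(gxp[:, pad:pad + L])

    return _make(out_data, (x, w, b), backward)


def maxpool1d(x, size=2):
    """Non-overlapping max pooling along axis 1; trailing remainder dropped."""
    x = _as_tensor(x)
    B, L, C = x.shape
    Lp = L // size
    xv = x.data[:, :Lp * size].reshape(B, Lp, size, C)
    idx = xv.argmax(axis=2)
    out_data = np.take_along_axis(xv, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(g):
        gx = np.zeros((B, Lp, size, C), dtype=g.dtype)
        np.put_along_axis(gx, idx[:, :, None, :], g[:, :, None, :], axis=2)
        full = np.zeros((B, L, C), dtype=g.dtype)
        full[:, :Lp * size] = gx.reshape(B, Lp * size, C)
        x._accumulate(full)

    return _make(out_data, (x,), backward)


# ----------------------------------------------------------------- optimizer

class Adam:
    """Adam with the standard defaults (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, params, lr=5e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
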