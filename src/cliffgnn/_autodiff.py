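"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The affinity model is small (tens of thousands of parameters, molecular
graphs with tens of atoms), so a tape of dense float64 NumPy operations is
fast enough for training and for gradient-based attribution while keeping
the whole numerical stack inspectable.  Only the operations the model needs
are implemented; every op defines its vector-Jacobian product in closed
form and is exercised by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter"]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, value, requires_grad=False, parents=(), vjp=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._vjp = vjp

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.value.shape

    def detach(self):
        return Tensor(self.value)

    def backward(self, seed=None):
        """Accumulate gradients of this (scalar) tensor into the graph leaves."""
        if seed is None:
            if self.value.size != 1:
                raise ValueError("backward() without seed requires a scalar output")
            seed = np.ones_like(self.value)
        order = []
        seen = set()
        stack = [(self, False)]
        while stack:  # iterative topological sort: graphs can be deep
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in order:
            node.grad = None
        self.grad = np.asarray(seed, dtype=np.float64)
        for node in reversed(order):
            if node._vjp is None or node.grad is None:
                continue
            for parent, contrib in node._vjp(node.grad):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.value)
                parent.grad = parent.grad + contrib

    # -------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x):
    return Tensor(x)


def parameter(x):
    return Tensor(x, requires_grad=True)


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------- primitives
def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.value + b.value, parents=(a, b))
    out._vjp = lambda g: (
        (a, _unbroadcast(g, a.value.shape)),
        (b, _unbroadcast(g, b.value.shape)),
    )
    return out


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.value * b.value, parents=(a, b))
    out._vjp = lambda g: (
        (a, _unbroadcast(g * b.value, a.value.shape)),
        (b, _unbroadcast(g * a.value, b.value.shape)),
    )
    return out


def div(a, b):
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.value / b.value, parents=(a, b))
    out._vjp = lambda g: (
        (a, _unbroadcast(g / b.value, a.value.shape)),
        (b, _unbroadcast(-g * a.value / (b.value**2), b.value.shape)),
    )
    return out


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.value @ b.value, parents=(a, b))

    def vjp(g):
        ga = g @ b.value.T if b.value.ndim == 2 else np.outer(g, b.value)
        gb = a.value.T @ g
        return ((a, ga.reshape(a.value.shape)), (b, gb.reshape(b.value.shape)))

    out._vjp = vjp
    return out


def bmm_vec(w, h):
    """Batched matrix-vector product: (m, d, d) x (m, d) -> (m, d)."""
    w, h = _wrap(w), _wrap(h)
    out = Tensor(np.einsum("mij,mj->mi", w.value, h.value), parents=(w, h))
    out._vjp = lambda g: (
        (w, np.einsum("mi,mj->mij", g, h.value)),
        (h, np.einsum("mij,mi->mj", w.value, g)),
    )
    return out


def getitem(a, key):
    a = _wrap(a)
    out = Tensor(a.value[key], parents=(a,))

    def vjp(g):
        ga = np.zeros_like(a.value)
        np.add.at(ga, key, g)
        return ((a, ga),)

    out._vjp = vjp
    return out


def gather_rows(a, idx):
    """Row gather a[idx] with scatter-add backward (idx may repeat)."""
    a = _wrap(a)
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(a.value[idx], parents=(a,))

    def vjp(g):
        ga = np.zeros_like(a.value)
        np.add.at(ga, idx, g)
        return ((a, ga),)

    out._vjp = vjp
    return out


def segment_sum(a, idx, n):
    """Sum rows of `a` into `n` buckets given by `idx`; backward is a gather."""
    a = _wrap(a)
    idx = np.asarray(idx, dtype=np.intp)
    val = np.zeros((n,) + a.value.shape[1:], dtype=np.float64)
    np.add.at(val, idx, a.value)
    out = Tensor(val, parents=(a,))
    out._vjp = lambda g: ((a, g[idx]),)
    return out


def concat(tensors, axis=0):
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        pieces = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, pieces))

    out._vjp = vjp
    return out


def reshape(a, shape):
    a = _wrap(a)
    out = Tensor(a.value.reshape(shape), parents=(a,))
    out._vjp = lambda g: ((a, g.reshape(a.value.shape)),)
    return out


def sum_(a, axis=None, keepdims=False):
    a = _wrap(a)
    out = Tensor(a.value.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def vjp(g):
        if axis is None:
            return ((a, np.broadcast_to(g, a.value.shape).copy()),)
        gg = g if keepdims else np.expand_dims(g, axis)
        return ((a, np.broadcast_to(gg, a.value.shape).copy()),)

    out._vjp = vjp
    return out


def mean_(a, axis=None, keepdims=False):
    a = _wrap(a)
    n = a.value.size if axis is None else a.value.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def relu(a):
    a = _wrap(a)
    mask = (a.value > 0).astype(np.float64)
    out = Tensor(a.value * mask, parents=(a,))
    out._vjp = lambda g: ((a, g * mask),)
    return out


def leaky_relu(a, slope=0.2):
    a = _wrap(a)
    scale = np.where(a.value > 0, 1.0, slope)
    out = Tensor(a.value * scale, parents=(a,))
    out._vjp = lambda g: ((a, g * scale),)
    return out


def exp(a):
    a = _wrap(a)
    val = np.exp(a.value)
    out = Tensor(val, parents=(a,))
    out._vjp = lambda g: ((a, g * val),)
    return out


def sqrt(a):
    a = _wrap(a)
    val = np.sqrt(a.value)
    out = Tensor(val, parents=(a,))
    out._vjp = lambda g: ((a, g * 0.5 / val),)
    return out


def square(a):
    a = _wrap(a)
    out = Tensor(a.value**2, parents=(a,))
    out._vjp = lambda g: ((a, g * 2.0 * a.value),)
    return out


def abs_(a):
    """|a| with subgradient 0 at 0 (the convention the penalties document)."""
    a = _wrap(a)
    out = Tensor(np.abs(a.value), parents=(a,))
    out._vjp = lambda g: ((a, g * np.sign(a.value)),)
    return out


def l2_norm(a, eps=0.0):
    """Euclidean norm of a flattened tensor; subgradient 0 at the origin."""
    a = _wrap(a)
    nrm = float(np.sqrt(np.sum(a.value**2)))
    out = Tensor(nrm, parents=(a,))

    def vjp(g):
        if nrm <= eps or nrm == 0.0:
            return ((a, np.zeros_like(a.value)),)
        return ((a, g * a.value / nrm),)

    out._vjp = vjp
    return out


def max_rows(a):
    """Row-wise reduction to the per-column max over axis 0 (n, d) -> (d,)."""
    a = _wrap(a)
    arg = np.argmax(a.value, axis=0)
    val = a.value[arg, np.arange(a.value.shape[1])]
    out = Tensor(val, parents=(a,))

    def vjp(g):
        ga = np.zeros_like(a.value)
        ga[arg, np.arange(a.value.shape[1])] = g
        return ((a, ga),)

    out._vjp = vjp
    return out
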