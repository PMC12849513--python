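"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations needed by the encoders, gates, critics and
classifier: broadcasting arithmetic, (batched) matmul, reductions, row
gather for embedding lookups, and the nonlinearities (sigmoid, GELU).
Everything is float64 so training histories are bitwise reproducible for a
fixed seed on a single thread.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "constant", "parameter", "concat", "softmax", "logsumexp"]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad = None
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- housekeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = (lambda g: (-g,)) if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        out._backward = bw if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = (
            (lambda g: (g * p * self.data ** (p - 1),)) if out.requires_grad else None
        )
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(np.matmul(self.data, other.data), _parents=(self, other))

        def bw(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        out._backward = bw if out.requires_grad else None
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))
        out._backward = (lambda g: (g * val,)) if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = (lambda g: (g / self.data,)) if out.requires_grad else None
        return out

    def sigmoid(self):
        val = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable sigmoid
        out = Tensor(val, _parents=(self,))
        out._backward = (lambda g: (g * val * (1.0 - val),)) if out.requires_grad else None
        return out

    def gelu(self):
        x = self.data
        phi = 0.5 * (1.0 + erf(x / _SQRT2))
        out = Tensor(x * phi, _parents=(self,))

        def bw(g):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
            return (g * (phi + x * pdf),)

        out._backward = bw if out.requires_grad else None
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        val = self.data.max(axis=axis, keepdims=True)
        out_val = val if keepdims else np.squeeze(val, axis=axis)
        # gradient routed to the first maximal element along the axis
        idx = np.argmax(self.data, axis=axis)
        out = Tensor(out_val, _parents=(self,))

        def bw(g):
            g = np.asarray(g)
            if keepdims:
                g = np.squeeze(g, axis=axis)
            grad = np.zeros_like(self.data)
            ix = list(np.indices(idx.shape))
            ix.insert(axis if axis >= 0 else self.data.ndim + axis, idx)
            grad[tuple(ix)] = g
            return (grad,)

        out._backward = bw if out.requires_grad else None
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = (lambda g: (g.reshape(self.shape),)) if out.requires_grad else None
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _parents=(self,))
        out._backward = (lambda g: (np.swapaxes(g, a, b),)) if out.requires_grad else None
        return out

    def take_rows(self, idx):
        """Gather rows along axis 0 (embedding lookup); scatter-add gradient."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, idx, g)
            return (grad,)

        out._backward = bw if out.requires_grad else None
        return out

    def diag(self):
        """Diagonal of a square matrix."""
        out = Tensor(np.diagonal(self.data).copy(), _parents=(self,))

        def bw(g):
            grad = np.zeros_like(self.data)
            np.fill_diagonal(grad, g)
            return (grad,)

        out._backward = bw if out.requires_grad else None
        return out

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:
                # leaf (parameter): accumulate
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def constant(data) -> Tensor:
    return Tensor(data)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = bw if out.requires_grad else None
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shift = t - constant(t.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def logsumexp(t: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = t.data.max(axis=axis, keepdims=True)
    shifted = (t - constant(m)).exp().sum(axis=axis, keepdims=True).log() + constant(m)
    if not keepdims:
        shifted = shifted.reshape(*np.squeeze(shifted.data, axis=axis).shape)
    return shifted
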