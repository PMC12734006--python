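"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ``numpy.ndarray`` and records the
operations applied to it; :meth:`Tensor.backward` walks the tape in
reverse topological order and accumulates gradients into ``.grad`` of
every tensor created with ``requires_grad=True``.

The op set is exactly what the fusion model needs: broadcast-aware
elementwise arithmetic, batched matmul, reductions, reshapes, the
activations (sigmoid, GELU, ReLU), a clamped log, a masked softmax that
returns an all-zero row when every position of a row is blocked, and
concatenation.  Every backward rule is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "tensor", "concat", "masked_softmax"]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e

        def backward(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self, floor: float | None = None):
        """Natural log; with ``floor`` the argument is clamped from below."""
        x = self.data if floor is None else np.maximum(self.data, floor)
        out_data = np.log(x)

        def backward(g):
            if self.requires_grad:
                gx = g / x
                if floor is not None:
                    gx = np.where(self.data >= floor, gx, 0.0)
                self._accum(gx)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable sigmoid

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        out_data = x * cdf

        def backward(g):
            if self.requires_grad:
                pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
                self._accum(g * (cdf + x * pdf))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0.0))

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- reductions and shape ops --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        return Tensor._make(out_data, (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(out_data, tuple(tensors), backward)


def masked_softmax(x: Tensor, keep: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over the positions where ``keep`` is True.

    Blocked positions get probability exactly 0.  A row in which every
    position is blocked yields an all-zero row rather than NaN, which is
    the fallback the fusion module relies on for absent modalities.
    """
    keep = np.broadcast_to(np.asarray(keep, dtype=bool), x.data.shape)
    logits = np.where(keep, x.data, -np.inf)
    m = np.max(logits, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.where(keep, np.exp(logits - m), 0.0)
    s = e.sum(axis=axis, keepdims=True)
    out_data = np.divide(e, s, out=np.zeros_like(e), where=s > 0)

    def backward(g):
        if x.requires_grad:
            inner = (g * out_data).sum(axis=axis, keepdims=True)
            x._accum((g - inner) * out_data)

    return Tensor._make(out_data, (x,), backward)
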