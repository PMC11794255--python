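"""Reverse-mode automatic differentiation over NumPy arrays.

A tape-based engine in the micrograd style, extended to n-d arrays with
broadcasting, batched matmul, reductions, indexing and concatenation —
the operation set the forecaster's computation graph needs. Everything
runs at float64 so analytic gradients can be verified against central
finite differences to tight tolerances.

Only :class:`Tensor` and a handful of helper functions are public; the
model modules build their forward passes from these primitives and call
:meth:`Tensor.backward` on a scalar loss.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "softmax", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph.

    Parameters
    ----------
    data : array-like
        Values, stored as a float64 ndarray.
    requires_grad : bool
        Whether gradients accumulate into :attr:`grad` on backward.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------

    @classmethod
    def _make(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g, b.data.shape))
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g * a.data, b.data.shape))
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data / other.data, (self, other), None)
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g / b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(-g * a.data / b.data**2, b.data.shape))
            out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out = Tensor._make(self.data**p, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g * p * a.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g @ b.data.swapaxes(-1, -2), a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(a.data.swapaxes(-1, -2) @ g, b.data.shape))
            out._backward = backward
        return out

    # -- elementwise nonlinearities -------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = Tensor._make(val, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self, v=val: a._accum(g * v)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g / a.data)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor._make(val, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self, v=val: a._accum(g * (1.0 - v**2))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(val, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self, v=val: a._accum(g * v * (1.0 - v))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self, m=mask: a._accum(g * m)
        return out

    # -- reductions and reshaping ---------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            def backward(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor._make(self.data.reshape(*shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out

    def swapaxes(self, a1: int, a2: int):
        out = Tensor._make(self.data.swapaxes(a1, a2), (self,), None)
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.swapaxes(a1, a2))
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)
        if out.requires_grad:
            def backward(g, a=self, idx=idx):
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)
            out._backward = backward
        return out

    # -- backward pass ---------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this scalar through the recorded graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``.

    The max-shift is detached: softmax is invariant to constant shifts,
    so treating the shift as a constant leaves gradients exact.
    """
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = (x - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tuple(tensors), None)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def backward(g, parts=tuple(tensors), splits=splits, axis=axis):
            for t, piece in zip(parts, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tuple(tensors), None)
    if out.requires_grad:
        def backward(g, parts=tuple(tensors), axis=axis):
            for i, t in enumerate(parts):
                if t.requires_grad:
                    t._accum(np.take(g, i, axis=axis))
        out._backward = backward
    return out
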