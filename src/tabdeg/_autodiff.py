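"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the attentive tabular network: broadcasting
arithmetic, matmul, slicing/concat, the usual nonlinearities, reductions,
and a hook for custom ops with hand-written vector-Jacobian products
(used by sparsemax/entmax).  Float64 throughout for reproducibility.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["Tensor", "concat", "custom_op"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents")

    def __init__(self, data, parents: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] = lambda: None
        self._parents = parents

    # -- graph ------------------------------------------------------------

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            node._backward()

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def _back():
            self._accum(_unbroadcast(out.grad, self.data.shape))
            other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = _back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def _back():
            self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self**-1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, (self,))

        def _back():
            self._accum(out.grad * exponent * self.data ** (exponent - 1.0))

        out._backward = _back
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def _back():
            self._accum(out.grad @ other.data.T)
            other._accum(self.data.T @ out.grad)

        out._backward = _back
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], (self,))

        def _back():
            g = np.zeros_like(self.data)
            np.add.at(g, key, out.grad)
            self._accum(g)

        out._backward = _back
        return out

    # -- nonlinearities ---------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), (self,))

        def _back():
            self._accum(out.grad * out.data)

        out._backward = _back
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))

        def _back():
            self._accum(out.grad / self.data)

        out._backward = _back
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def _back():
            self._accum(out.grad * (self.data > 0))

        out._backward = _back
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))

        def _back():
            self._accum(out.grad * s * (1.0 - s))

        out._backward = _back
        return out

    def sqrt(self):
        return self**0.5

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def _back():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _back():
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.data.ndim
            sl[axis] = slice(start, stop)
            t._accum(out.grad[tuple(sl)])

    out._backward = _back
    return out


def custom_op(x: Tensor, forward: Callable, vjp: Callable) -> Tensor:
    """Apply ``forward`` to ``x.data``; ``vjp(y, grad)`` maps the output and
    the upstream gradient to the gradient with respect to the input."""
    y = forward(x.data)
    out = Tensor(y, (x,))

    def _back():
        x._accum(vjp(y, out.grad))

    out._backward = _back
    return out
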