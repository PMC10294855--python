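"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-based engine in the micrograd style, generalized to tensors: every
operation returns a :class:`Tensor` holding the forward value and a closure
that accumulates gradients into its parents. It supports exactly the
operations the recurrent/convolutional models in this package need
(element-wise arithmetic, matmul, activations, reductions, slicing,
concatenation, padding and time-axis upsampling) and is validated against
finite differences in the test suite.

All data is float64; gradients are dense ndarrays of the same shape.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "sigmoid",
    "tanh",
    "relu",
    "exp",
    "log",
    "pad_time",
    "repeat_time",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=None):
        arr = np.asarray(data, dtype=np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in self._parents)
        self.requires_grad = bool(requires_grad)

    # ---------------------------------------------------------------- basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _acc(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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

    # ------------------------------------------------------------ arithmetic
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            self._acc(_unbroadcast(g, self.data.shape))
            other._acc(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._acc(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            self._acc(_unbroadcast(g * other.data, self.data.shape))
            other._acc(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, (self, other))

        def backward(g):
            self._acc(_unbroadcast(g / other.data, self.data.shape))
            other._acc(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = backward
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, (self,))
        out._backward = lambda g: self._acc(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        out = Tensor(a @ b, (self, other))

        def backward(g):
            if a.ndim == 2 and b.ndim == 2:
                self._acc(g @ b.T)
                other._acc(a.T @ g)
            elif a.ndim == 3 and b.ndim == 2:
                self._acc(g @ b.T)
                other._acc(np.einsum("bti,bto->io", a, g))
            else:  # pragma: no cover - unsupported combination
                raise NotImplementedError(
                    f"matmul backward for ndims {a.ndim}@{b.ndim}"
                )

        out._backward = backward
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # --------------------------------------------------------- restructuring
    def __getitem__(self, key):
        out = Tensor(self.data[key], (self,))

        def backward(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._acc(full)

        out._backward = backward
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._acc(g.reshape(self.data.shape))
        return out


# ------------------------------------------------------------------ functions
def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, (x,))
    out._backward = lambda g: x._acc(g * (1.0 - y**2))
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = expit(x.data)
    out = Tensor(y, (x,))
    out._backward = lambda g: x._acc(g * y * (1.0 - y))
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))
    out._backward = lambda g: x._acc(g * (x.data > 0))
    return out


def exp(x: Tensor) -> Tensor:
    y = np.exp(x.data)
    out = Tensor(y, (x,))
    out._backward = lambda g: x._acc(g * y)
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), (x,))
    out._backward = lambda g: x._acc(g / x.data)
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis if axis >= 0 else g.ndim + axis] = slice(a, b)
            t._acc(g[tuple(idx)])

    out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))

    def backward(g):
        for i, t in enumerate(tensors):
            t._acc(np.take(g, i, axis=axis))

    out._backward = backward
    return out


def pad_time(x: Tensor, left: int, right: int) -> Tensor:
    """Zero-pad a (batch, time, channels) tensor along the time axis."""
    out = Tensor(
        np.pad(x.data, ((0, 0), (left, right), (0, 0))), (x,)
    )

    def backward(g):
        stop = g.shape[1] - right if right else None
        x._acc(g[:, left:stop, :])

    out._backward = backward
    return out


def repeat_time(x: Tensor, r: int) -> Tensor:
    """Repeat each time step ``r`` times (nearest-neighbour upsampling)."""
    out = Tensor(np.repeat(x.data, r, axis=1), (x,))

    def backward(g):
        b, t, c = x.data.shape
        x._acc(g.reshape(b, t, r, c).sum(axis=2))

    out._backward = backward
    return out
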