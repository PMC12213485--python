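"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps a float64
``numpy`` array and records the operation that produced it, so a single call to
:meth:`Tensor.backward` accumulates gradients through arbitrary compositions of
the ops defined here (elementwise arithmetic, broadcasting, matmul with batch
dimensions, reductions, reshapes and basic slicing).  Float64 is used
throughout: the models in this package are small enough that precision is worth
more than speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class _GradMode:
    enabled = True


class no_grad:
    """Context manager disabling graph construction (eval-mode forward passes)."""

    def __enter__(self):
        self._prev = _GradMode.enabled
        _GradMode.enabled = False
        return self

    def __exit__(self, *exc):
        _GradMode.enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev if _GradMode.enabled else ()

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph construction ------------------------------------------------
    def _make(self, data, parents, backward):
        out = Tensor(data, _prev=parents if _GradMode.enabled else ())
        if _GradMode.enabled:
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = self._make(self.data + other.data, (self, other), None)
        def backward(g):
            return _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = self._make(self.data * other.data, (self, other), None)
        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = self._make(self.data / other.data, (self, other), None)
        def backward(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.data.shape))
        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = self._make(self.data ** exponent, (self,), None)
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self._make(self.data @ other.data, (self, other), None)
        def backward(g):
            ga = _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape)
            gb = _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape)
            return ga, gb
        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)
        out._backward = backward
        return out

    # -- elementwise functions ----------------------------------------------
    def exp(self):
        value = np.exp(self.data)
        out = self._make(value, (self,), None)
        out._backward = lambda g: (g * value,)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        value = np.sqrt(self.data)
        out = self._make(value, (self,), None)
        out._backward = lambda g: (g / (2.0 * value),)
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)
        out._backward = lambda g: (g * mask,)
        return out

    def tanh(self):
        value = np.tanh(self.data)
        out = self._make(value, (self,), None)
        out._backward = lambda g: (g * (1.0 - value ** 2),)
        return out

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / count

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def transpose(self, *axes):
        inverse = np.argsort(axes)
        out = self._make(self.data.transpose(axes), (self,), None)
        out._backward = lambda g: (g.transpose(inverse),)
        return out

    def swapaxes(self, a: int, b: int):
        out = self._make(np.swapaxes(self.data, a, b), (self,), None)
        out._backward = lambda g: (np.swapaxes(g, a, b),)
        return out

    # -- composite helpers -----------------------------------------------------
    def softmax(self, axis: int = -1):
        """Numerically stable softmax along ``axis`` (max-shift is detached)."""
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- backward pass ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._prev:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._prev, node._backward(g)):
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)
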