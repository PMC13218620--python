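"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the fusion similarity network: broadcasting
arithmetic, 2-D matrix products, elementwise nonlinearities, reductions,
reshape and concatenation.  Gradients are accumulated on a topologically
ordered tape; correctness is checked against finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "relu", "sigmoid"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _child(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return self._child(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._child(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            return _unbroadcast(g * other.data, self.shape), _unbroadcast(g * self.data, other.shape)

        return self._child(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._child(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def backward(g):
            return g @ other.data.T, self.data.T @ g

        return self._child(self.data @ other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return self._child(self.data**exponent, (self,), backward)

    def abs(self):
        def backward(g):
            return (g * np.sign(self.data),)

        return self._child(np.abs(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return self._child(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- reductions and reshaping ---------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.full(self.shape, g),)
            g_arr = np.asarray(g)
            if not keepdims:
                g_arr = np.expand_dims(g_arr, axis)
            return (np.broadcast_to(g_arr, self.shape).copy(),)

        return self._child(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g):
            return (g.reshape(self.shape),)

        return self._child(self.data.reshape(*shape), (self,), backward)

    # -- autodiff driver -------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        visited: set[int] = set()

        def build(t: Tensor):
            if id(t) in visited or not t.requires_grad:
                return
            visited.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for parent, g in zip(t._parents, grads):
                if parent.requires_grad:
                    parent.grad = parent.grad + g if parent.grad is not None else np.asarray(g)


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0

    def backward(g):
        return (g * mask,)

    return t._child(t.data * mask, (t,), backward)


def sigmoid(t: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-np.clip(t.data, -60, 60)))

    def backward(g):
        return (g * out_data * (1.0 - out_data),)

    return t._child(out_data, (t,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(np.concatenate(datas, axis=axis), requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)

        def backward(g):
            return tuple(np.split(g, splits, axis=axis))

        out._backward = backward
    return out
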