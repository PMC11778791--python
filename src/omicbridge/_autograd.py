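"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the training losses need: broadcast
arithmetic, matmul, ReLU, exp/log/sqrt, axis reductions, row-max (with
argmax subgradient) and an Adam optimizer.  Gradients are verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "relu", "exp", "log", "sqrt", "row_max"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("value", "grad", "_backward", "_parents", "requires_grad")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.value.shape

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, value, parents, backward) -> "Tensor":
        out = Tensor(value)
        out.requires_grad = any(p.requires_grad or p._parents for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # ---- arithmetic -------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_val = self.value + other.value

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_val, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.value, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_val = self.value * other.value

        def backward(g):
            return (
                _unbroadcast(g * other.value, self.shape),
                _unbroadcast(g * self.value, other.shape),
            )

        return self._make(out_val, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_val = self.value / other.value

        def backward(g):
            return (
                _unbroadcast(g / other.value, self.shape),
                _unbroadcast(-g * self.value / other.value**2, other.shape),
            )

        return self._make(out_val, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_val = self.value**p

        def backward(g):
            return (g * p * self.value ** (p - 1),)

        return self._make(out_val, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_val = self.value @ other.value

        def backward(g):
            return (g @ other.value.T, self.value.T @ g)

        return self._make(out_val, (self, other), backward)

    # ---- shape ------------------------------------------------------
    @property
    def T(self):
        return self._make(self.value.T, (self,), lambda g: (g.T,))

    def reshape(self, *shape):
        old = self.shape
        return self._make(
            self.value.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def sum(self, axis=None, keepdims: bool = False):
        out_val = self.value.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return self._make(out_val, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.value.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def rows(self, start: int, stop: int):
        """Slice rows [start:stop]; gradient scatters back into place."""
        shape = self.shape

        def backward(g):
            full = np.zeros(shape)
            full[start:stop] = g
            return (full,)

        return self._make(self.value[start:stop], (self,), backward)

    # ---- autodiff driver --------------------------------------------
    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.value)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None or t._backward is None:
                if g is not None and t.requires_grad:
                    t.grad = g if t.grad is None else t.grad + g
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            for parent, pg in zip(t._parents, t._backward(g)):
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


# ---- elementwise functions ------------------------------------------


def relu(t: Tensor) -> Tensor:
    mask = t.value > 0
    return t._make(t.value * mask, (t,), lambda g: (g * mask,))


def exp(t: Tensor) -> Tensor:
    out_val = np.exp(t.value)
    return t._make(out_val, (t,), lambda g: (g * out_val,))


def log(t: Tensor) -> Tensor:
    return t._make(np.log(t.value), (t,), lambda g: (g / t.value,))


def sqrt(t: Tensor) -> Tensor:
    out_val = np.sqrt(t.value)
    return t._make(out_val, (t,), lambda g: (g / (2.0 * out_val),))


def row_max(t: Tensor) -> Tensor:
    """Max over the last axis; gradient flows to the argmax entry only."""
    idx = np.argmax(t.value, axis=-1)
    out_val = np.take_along_axis(t.value, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        full = np.zeros_like(t.value)
        np.put_along_axis(full, idx[..., None], np.asarray(g)[..., None], axis=-1)
        return (full,)

    return t._make(out_val, (t,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
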