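"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the encoder forward passes and the
distillation losses need: broadcasting arithmetic, batched matmul,
exp/log/tanh/erf/relu, reductions, reshaping, indexing, concatenation and
embedding lookup.  Everything is float64; gradients are accumulated with
``+=`` so a tensor used twice receives the sum of both paths.

Gradient flow is pruned at tensors with ``requires_grad=False`` (and at
anything built only from such tensors), which is how frozen teachers are
kept out of the backward pass.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "as_tensor", "parameter", "concat", "embedding", "softmax", "layer_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      _parents=parents if req else (),
                      _backward=backward if req else None)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor._make(self.data ** exponent, (self,), None)
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data @ other.data, (self, other), None)

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        out = Tensor._make(out_data, (self,), None)
        out._backward = lambda g: (g * out_data,)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)
        out._backward = lambda g: (g / self.data,)
        return out

    def tanh(self):
        out_data = np.tanh(self.data)
        out = Tensor._make(out_data, (self,), None)
        out._backward = lambda g: (g * (1.0 - out_data ** 2),)
        return out

    def erf(self):
        out = Tensor._make(_erf(self.data), (self,), None)
        out._backward = lambda g: (g * (2.0 / np.sqrt(np.pi)) * np.exp(-self.data ** 2),)
        return out

    def relu(self):
        out = Tensor._make(np.maximum(self.data, 0.0), (self,), None)
        out._backward = lambda g: (g * (self.data > 0),)
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        out = Tensor._make(self.data.reshape(*shape), (self,), None)
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        out = Tensor._make(self.data.transpose(*axes), (self,), None)
        inv = np.argsort(axes)
        out._backward = lambda g: (g.transpose(*inv),)
        return out

    def swapaxes(self, a, b):
        out = Tensor._make(np.swapaxes(self.data, a, b), (self,), None)
        out._backward = lambda g: (np.swapaxes(g, a, b),)
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = backward
        return out

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for parent, g in zip(t._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), None)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)
    out = Tensor._make(weight.data[ids], (weight,), None)

    def backward(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
        return (full,)

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # max-shift is a constant w.r.t. the gradient
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-12) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * weight + bias
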