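"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the toy transformer encoder and BiLSTM-CRF
need: broadcast arithmetic, (batched) matmul, pointwise nonlinearities,
reductions, softmax/log-sum-exp, indexing/gather, concatenation and
reshaping, plus an Adam optimizer.  Gradients are accumulated on ``Tensor``
leaves after calling :meth:`Tensor.backward` on a scalar result.

This is deliberately small: float64 only, no in-place ops, no graph reuse.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_graph(*tensors: Tensor) -> bool:
    return _GRAD_ENABLED and any(
        t.requires_grad or t._parents or t._backward for t in tensors
    )


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = parents
        out._backward = backward
    return out


# -- arithmetic -------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data
    return _make(
        data,
        (a, b),
        lambda g: [(a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape))],
    )


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data
    return _make(
        data,
        (a, b),
        lambda g: [
            (a, _unbroadcast(g * b.data, a.shape)),
            (b, _unbroadcast(g * a.data, b.shape)),
        ],
    )


def neg(a) -> Tensor:
    a = _as_tensor(a)
    return _make(-a.data, (a,), lambda g: [(a, -g)])


def sub(a, b) -> Tensor:
    return add(a, neg(b))


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data / b.data
    return _make(
        data,
        (a, b),
        lambda g: [
            (a, _unbroadcast(g / b.data, a.shape)),
            (b, _unbroadcast(-g * a.data / (b.data**2), b.shape)),
        ],
    )


def matmul(a, b) -> Tensor:
    """Matrix product; operands must be at least 2-D (batch dims broadcast)."""
    a, b = _as_tensor(a), _as_tensor(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires >=2-D operands; reshape vectors first")
    data = a.data @ b.data

    def backward(g: np.ndarray):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return [(a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape))]

    return _make(data, (a, b), backward)


def pow_(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data**exponent
    return _make(
        data, (a,), lambda g: [(a, g * exponent * a.data ** (exponent - 1))]
    )


# -- pointwise nonlinearities ----------------------------------------------


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)
    return _make(data, (a,), lambda g: [(a, g * data)])


def log(a) -> Tensor:
    a = _as_tensor(a)
    return _make(np.log(a.data), (a,), lambda g: [(a, g / a.data)])


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    data = np.tanh(a.data)
    return _make(data, (a,), lambda g: [(a, g * (1.0 - data**2))])


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))
    return _make(data, (a,), lambda g: [(a, g * data * (1.0 - data))])


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    return _make(a.data * mask, (a,), lambda g: [(a, g * mask)])


# -- reductions and normalisers ---------------------------------------------


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g: np.ndarray):
        if axis is None:
            return [(a, np.broadcast_to(g, a.shape).copy())]
        gg = g if keepdims else np.expand_dims(g, axis)
        return [(a, np.broadcast_to(gg, a.shape).copy())]

    return _make(data, (a,), backward)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g: np.ndarray):
        inner = (g * data).sum(axis=axis, keepdims=True)
        return [(a, data * (g - inner))]

    return _make(data, (a,), backward)


def logsumexp(a, axis: int = -1, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    s = e.sum(axis=axis, keepdims=True)
    data = (m + np.log(s)).squeeze(axis) if not keepdims else m + np.log(s)

    def backward(g: np.ndarray):
        gg = g if keepdims else np.expand_dims(g, axis)
        return [(a, gg * (e / s))]

    return _make(data, (a,), backward)


# -- shape ops ---------------------------------------------------------------


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    return _make(
        a.data.reshape(shape), (a,), lambda g: [(a, g.reshape(a.shape))]
    )


def swapaxes(a, ax1: int, ax2: int) -> Tensor:
    a = _as_tensor(a)
    return _make(
        np.swapaxes(a.data, ax1, ax2),
        (a,),
        lambda g: [(a, np.swapaxes(g, ax1, ax2))],
    )


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray):
        parts = np.split(g, splits, axis=axis)
        return list(zip(tensors, parts))

    return _make(data, tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g: np.ndarray):
        parts = np.split(g, len(tensors), axis=axis)
        return [(t, p.squeeze(axis)) for t, p in zip(tensors, parts)]

    return _make(data, tuple(tensors), backward)


def take(a, index) -> Tensor:
    """Gather rows/elements: out = a.data[index] (integer or slice index)."""
    a = _as_tensor(a)
    data = a.data[index]

    def backward(g: np.ndarray):
        full = np.zeros_like(a.data)
        np.add.at(full, index, g)
        return [(a, full)]

    return _make(data, (a,), backward)


# -- operator sugar -----------------------------------------------------------

Tensor.__add__ = lambda self, other: add(self, other)
Tensor.__radd__ = lambda self, other: add(other, self)
Tensor.__sub__ = lambda self, other: sub(self, other)
Tensor.__rsub__ = lambda self, other: sub(other, self)
Tensor.__mul__ = lambda self, other: mul(self, other)
Tensor.__rmul__ = lambda self, other: mul(other, self)
Tensor.__truediv__ = lambda self, other: div(self, other)
Tensor.__neg__ = lambda self: neg(self)
Tensor.__matmul__ = lambda self, other: matmul(self, other)
Tensor.__pow__ = lambda self, e: pow_(self, e)
Tensor.__getitem__ = lambda self, idx: take(self, idx)
Tensor.sum = lambda self, axis=None, keepdims=False: sum_(self, axis, keepdims)
Tensor.mean = lambda self, axis=None, keepdims=False: mean(self, axis, keepdims)
Tensor.reshape = lambda self, *shape: reshape(
    self, shape[0] if len(shape) == 1 and isinstance(shape[0], (tuple, list)) else shape
)


def parameter(data, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """A trainable leaf tensor; if ``scale`` given, data is a shape tuple to
    initialise uniformly in [-scale, scale] using ``rng``."""
    if scale is not None:
        assert rng is not None
        data = rng.uniform(-scale, scale, size=data)
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-2,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
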