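"""Minimal reverse-mode automatic differentiation over numpy arrays.

The forecaster in this package is a small model (a handful of variable
tokens, embedding widths of a few dozen), so a compact tape-based autodiff
engine is all that is needed to train it. :class:`Tensor` wraps a numpy
array, records the operations applied to it, and :meth:`Tensor.backward`
accumulates gradients by walking the tape in reverse topological order.

Only the operations the model uses are implemented: broadcast add/mul,
matmul (with batch broadcasting), elementwise nonlinearities, softmax,
reductions, reshape/transpose/concat/slice. The free functions
(:func:`relu`, :func:`sigmoid`, :func:`softmax`, :func:`concat`, ...)
dispatch on the argument type, so the same model code runs on plain numpy
arrays (inference, oracles) and on tensors (training).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "sigmoid",
    "exp",
    "softmax",
    "concat",
    "matmul",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / b.data**2, b.data.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __pow__(self, p: float):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.full_like(a.data, 1.0) * g)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a1: int, a2: int):
        axes = list(range(self.data.ndim))
        axes[a1], axes[a2] = axes[a2], axes[a1]
        return self.transpose(tuple(axes))

    def __getitem__(self, idx):
        def backward(g, a=self):
            if a.requires_grad:
                buf = np.zeros_like(a.data)
                np.add.at(buf, idx, g)
                a._accum(buf)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- dispatching functional ops (work on Tensor and ndarray alike) ------------

def relu(x):
    if isinstance(x, Tensor):
        mask = x.data > 0

        def backward(g, a=x):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(np.maximum(x.data, 0.0), (x,), backward)
    return np.maximum(x, 0.0)


def exp(x):
    if isinstance(x, Tensor):
        out_data = np.exp(x.data)

        def backward(g, a=x, o=out_data):
            if a.requires_grad:
                a._accum(g * o)

        return Tensor._make(out_data, (x,), backward)
    return np.exp(x)


def sigmoid(x):
    if isinstance(x, Tensor):
        out_data = 1.0 / (1.0 + np.exp(-x.data))

        def backward(g, a=x, o=out_data):
            if a.requires_grad:
                a._accum(g * o * (1.0 - o))

        return Tensor._make(out_data, (x,), backward)
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _softmax_np(x: np.ndarray, axis: int) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax(x, axis: int = -1):
    if isinstance(x, Tensor):
        out_data = _softmax_np(x.data, axis)

        def backward(g, a=x, o=out_data):
            if a.requires_grad:
                dot = (g * o).sum(axis=axis, keepdims=True)
                a._accum(o * (g - dot))

        return Tensor._make(out_data, (x,), backward)
    return _softmax_np(np.asarray(x, dtype=float), axis)


def concat(parts, axis: int = -1):
    if any(isinstance(p, Tensor) for p in parts):
        parts = [as_tensor(p) for p in parts]
        sizes = [p.data.shape[axis] for p in parts]
        offsets = np.cumsum([0] + sizes)

        def backward(g, ps=parts, offs=offsets):
            for p, lo, hi in zip(ps, offs[:-1], offs[1:]):
                if p.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    p._accum(g[tuple(sl)])

        data = np.concatenate([p.data for p in parts], axis=axis)
        return Tensor._make(data, tuple(parts), backward)
    return np.concatenate(parts, axis=axis)


def matmul(a, b):
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        return as_tensor(a) @ as_tensor(b)
    return a @ b


class Adam:
    """Adam optimizer over a list of :class:`Tensor` parameters."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
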