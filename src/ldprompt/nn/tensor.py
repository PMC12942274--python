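"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the miniature models need: broadcasted
arithmetic, matmul, pointwise nonlinearities, reductions, reshaping/indexing,
2-D convolution (via im2col), padding, and fixed bilinear resampling.  All
arrays are float64 and every operation is deterministic, so forward passes are
bit-reproducible under a fixed seed and single-threaded BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "log_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("pass Tensor.data, not Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name", "lr_scale")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name: str | None = None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def __float__(self):
        return float(self.data)

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                self._accum(_matmul_grad_a(g, self.data, other.data))
            if other.requires_grad:
                other._accum(_matmul_grad_b(g, self.data, other.data))

        return self._make(out_data, (self, other), backward)

    # -- pointwise --------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable sigmoid

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    def maximum(self, other):
        other = Tensor._lift(other)
        take_self = self.data >= other.data
        out_data = np.where(take_self, self.data, other.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * take_self)
            if other.requires_grad:
                other._accum(g * (~take_self))

        return self._make(out_data, (self, other), backward)

    def minimum(self, other):
        other = Tensor._lift(other)
        take_self = self.data <= other.data
        out_data = np.where(take_self, self.data, other.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * take_self)
            if other.requires_grad:
                other._accum(g * (~take_self))

        return self._make(out_data, (self, other), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), backward)


def _matmul_grad_a(g, a, b):
    ga = np.matmul(g, np.swapaxes(b, -1, -2))
    return _unbroadcast(ga, a.shape)


def _matmul_grad_b(g, a, b):
    gb = np.matmul(np.swapaxes(a, -1, -2), g)
    return _unbroadcast(gb, b.shape)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()
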