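"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the forecasting networks need: broadcasted
arithmetic, matmul, the usual pointwise nonlinearities, reductions, slicing,
concatenation and stacking. Gradients are accumulated into ``.grad`` by
:meth:`Tensor.backward`, which topologically sorts the tape.

All computation is float64 and single-threaded numpy, so results are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "sigmoid", "tanh", "relu", "exp", "log", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` back down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum along broadcast (size-1) axes
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # ---- housekeeping ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ---- autograd driver -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS post-order (graphs can be deep for long GRU rollouts)
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        stack_ = visiting
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack_.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bw(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bw(g):
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def _bw(g):
            self._accum(g * p * self.data ** (p - 1.0))
        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bw(g):
            if self.requires_grad or self._prev:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad or other._prev:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = _bw
        return out

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def _bw(g):
            self._accum(g.reshape(self.data.shape))
        out._backward = _bw
        return out

    def transpose(self, *axes):
        axes = axes or tuple(range(self.ndim))[::-1]
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def _bw(g):
            self._accum(g.transpose(inv))
        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        out._backward = _bw
        return out

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max reduction; gradient flows to the (first) argmax elements."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, self.requires_grad, (self,))
        mask = self.data == self.data.max(axis=axis, keepdims=True)
        # split ties evenly so the subgradient stays bounded
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def _bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(mask * g)
        out._backward = _bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))

        def _bw(g):
            self._accum(g * np.sign(self.data))
        out._backward = _bw
        return out


# ---- functional ops -------------------------------------------------------

def _unary(x: Tensor, fwd, dfd) -> Tensor:
    x = Tensor._lift(x)
    y = fwd(x.data)
    out = Tensor(y, x.requires_grad, (x,))

    def _bw(g):
        x._accum(g * dfd(x.data, y))
    out._backward = _bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    def fwd(d):
        out = np.empty_like(d)
        pos = d >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
        e = np.exp(d[~pos])
        out[~pos] = e / (1.0 + e)
        return out
    return _unary(x, fwd, lambda d, y: y * (1.0 - y))


def tanh(x: Tensor) -> Tensor:
    return _unary(x, np.tanh, lambda d, y: 1.0 - y * y)


def relu(x: Tensor) -> Tensor:
    return _unary(x, lambda d: np.maximum(d, 0.0), lambda d, y: (d > 0).astype(np.float64))


def exp(x: Tensor) -> Tensor:
    return _unary(x, np.exp, lambda d, y: y)


def log(x: Tensor) -> Tensor:
    return _unary(x, np.log, lambda d, y: 1.0 / d)


def softplus(x: Tensor) -> Tensor:
    """log(1 + e^x), computed stably; used by the cross-entropy losses."""
    return _unary(x, lambda d: np.logaddexp(0.0, d), lambda d, y: 1.0 / (1.0 + np.exp(-d)))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])
    out._backward = _bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))

    def _bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))
    out._backward = _bw
    return out
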