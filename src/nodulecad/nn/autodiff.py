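"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps an
``ndarray`` and records, for every operation, a closure that propagates
the output gradient to the operation's inputs.  ``Tensor.backward``
topologically sorts the tape and runs the closures in reverse.

Only the operations the networks in this package need are provided
(elementwise arithmetic, matmul, reductions, reshaping, concatenation,
gather, and the activation functions).  Convolution, pooling and batch
normalisation live in :mod:`nodulecad.nn.layers` as primitives with
hand-written backward passes built on the same mechanism.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "log",
    "exp",
    "sigmoid",
    "relu",
    "absolute",
    "concat",
    "gather",
    "matmul",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = ()):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = None

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a seed gradient needs a scalar")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def _bwd(g, a=self, b=other):
                if a.requires_grad:
                    a.accumulate(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b.accumulate(_unbroadcast(g, b.data.shape))
            out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a.accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def _bwd(g, a=self, b=other):
                if a.requires_grad:
                    a.accumulate(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad:
                    b.accumulate(_unbroadcast(g * a.data, b.data.shape))
            out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def _bwd(g, a=self, b=other):
                if a.requires_grad:
                    a.accumulate(_unbroadcast(g / b.data, a.data.shape))
                if b.requires_grad:
                    b.accumulate(_unbroadcast(-g * a.data / b.data**2, b.data.shape))
            out._backward = _bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = _make(self.data**exponent, (self,))
        if out.requires_grad:
            def _bwd(g, a=self, e=exponent):
                a.accumulate(g * e * a.data ** (e - 1))
            out._backward = _bwd
        return out

    # -- reductions / shaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def _bwd(g, a=self, ax=axis, kd=keepdims):
                if ax is not None and not kd:
                    g = np.expand_dims(g, ax)
                a.accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))
            out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a.accumulate(g.reshape(a.data.shape))
        return out

    def transpose(self, axes):
        out = _make(self.data.transpose(axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g, a=self, inv=tuple(inv): a.accumulate(
                g.transpose(inv)
            )
        return out


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents if req else ())


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- functions ---------------------------------------------------------

def log(x):
    """Natural log; dispatches on ndarray vs Tensor."""
    if not isinstance(x, Tensor):
        return np.log(x)
    out = _make(np.log(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g, a=x: a.accumulate(g / a.data)
    return out


def exp(x):
    if not isinstance(x, Tensor):
        return np.exp(x)
    out = _make(np.exp(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g, a=x, d=out.data: a.accumulate(g * d)
    return out


def sigmoid(x):
    if not isinstance(x, Tensor):
        return 1.0 / (1.0 + np.exp(-x))
    val = 1.0 / (1.0 + np.exp(-x.data))
    out = _make(val, (x,))
    if out.requires_grad:
        out._backward = lambda g, a=x, v=val: a.accumulate(g * v * (1.0 - v))
    return out


def relu(x):
    if not isinstance(x, Tensor):
        return np.maximum(x, 0.0)
    out = _make(np.maximum(x.data, 0.0), (x,))
    if out.requires_grad:
        mask = (x.data > 0).astype(np.float32)
        out._backward = lambda g, a=x, m=mask: a.accumulate(g * m)
    return out


def absolute(x):
    if not isinstance(x, Tensor):
        return np.abs(x)
    out = _make(np.abs(x.data), (x,))
    if out.requires_grad:
        sign = np.sign(x.data).astype(np.float32)
        out._backward = lambda g, a=x, s=sign: a.accumulate(g * s)
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bwd(g, ts=tensors, sp=splits, ax=axis):
            for t, piece in zip(ts, np.split(g, sp, axis=ax)):
                if t.requires_grad:
                    t.accumulate(piece)

        out._backward = _bwd
    return out


def gather(x: Tensor, index, axis: int = 0) -> Tensor:
    """Select rows (or slices along ``axis``) by integer index."""
    index = np.asarray(index, dtype=np.intp)
    out = _make(np.take(x.data, index, axis=axis), (x,))
    if out.requires_grad:
        def _bwd(g, a=x, idx=index, ax=axis):
            full = np.zeros_like(a.data)
            np.add.at(full, (slice(None),) * ax + (idx,), g)
            a.accumulate(full)
        out._backward = _bwd
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _make(a.data @ b.data, (a, b))
    if out.requires_grad:
        def _bwd(g, x=a, y=b):
            if x.requires_grad:
                x.accumulate(g @ y.data.T)
            if y.requires_grad:
                y.accumulate(x.data.T @ g)
        out._backward = _bwd
    return out
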