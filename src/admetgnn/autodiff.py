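"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The graph layers in :mod:`admetgnn.layers` are built from a small set of
differentiable primitives (matmul, broadcast add/mul, LeakyReLU, sigmoid,
exp/log, reductions, reshape/transpose/concat).  This module provides exactly
that set: a :class:`Tensor` wrapping an ``ndarray`` plus a backward closure,
and a topological-order backward pass.  Gradients of broadcast operations are
reduced back to the operand's shape with :func:`_unbroadcast`.

All gradients are checked against central finite differences in the test
suite; the engine is deliberately eager and single-threaded.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "leaky_relu", "sigmoid",
           "exp", "log", "maximum_with_mask", "masked_softmax", "matmul",
           "clip_values", "sqrt"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    """A node in the computation graph.

    Parameters with ``requires_grad=True`` accumulate gradients in ``.grad``
    after :meth:`backward` is called on a scalar downstream node.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            self._accum(g)
            other._accum(g)

        out._backward = backward if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = (lambda g: self._accum(-g)) if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = backward if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data ** 2)

        out._backward = backward if out.requires_grad else None
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = backward if out.requires_grad else None
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = (lambda g: self._accum(g.reshape(orig))) if out.requires_grad else None
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = (lambda g: self._accum(g.transpose(inv))) if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = backward if out.requires_grad else None
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = backward if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(np.asarray(value))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with NumPy stacked-batch semantics."""
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        a._accum(g @ np.swapaxes(b.data, -1, -2))
        b._accum(np.swapaxes(a.data, -1, -2) @ g)

    out._backward = backward if out.requires_grad else None
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    x = as_tensor(x)
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, slope * x.data), parents=(x,))
    out._backward = (lambda g: x._accum(np.where(pos, g, slope * g))) if out.requires_grad else None
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))
    out._backward = (lambda g: x._accum(g * s * (1.0 - s))) if out.requires_grad else None
    return out


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    e = np.exp(x.data)
    out = Tensor(e, parents=(x,))
    out._backward = (lambda g: x._accum(g * e)) if out.requires_grad else None
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data), parents=(x,))
    out._backward = (lambda g: x._accum(g / x.data)) if out.requires_grad else None
    return out


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    r = np.sqrt(x.data)
    out = Tensor(r, parents=(x,))
    out._backward = (lambda g: x._accum(g * 0.5 / r)) if out.requires_grad else None
    return out


def clip_values(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip with straight-through zero gradient outside [lo, hi]."""
    x = as_tensor(x)
    inside = (x.data >= lo) & (x.data <= hi)
    out = Tensor(np.clip(x.data, lo, hi), parents=(x,))
    out._backward = (lambda g: x._accum(np.where(inside, g, 0.0))) if out.requires_grad else None
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = backward if out.requires_grad else None
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))

    def backward(g):
        for t, piece in zip(tensors, np.moveaxis(g, axis, 0)):
            t._accum(piece)

    out._backward = backward if out.requires_grad else None
    return out


def maximum_with_mask(x: Tensor, mask: np.ndarray, fill: float) -> Tensor:
    """Replace entries where ``mask`` is False by the constant ``fill``.

    Gradient flows only through retained entries; used to exclude non-edges
    from the attention softmax.
    """
    x = as_tensor(x)
    keep = np.asarray(mask, dtype=bool)
    out = Tensor(np.where(keep, x.data, fill), parents=(x,))
    out._backward = (lambda g: x._accum(np.where(keep, g, 0.0))) if out.requires_grad else None
    return out


def masked_softmax(scores: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over ``axis`` restricted to entries where ``mask`` is nonzero.

    Rows whose mask is entirely zero produce all-zero output rows (the
    convention for padded atoms and atoms outside a substructure).
    """
    keep = np.asarray(mask, dtype=bool)
    neg = np.finfo(scores.data.dtype).min / 4
    masked = maximum_with_mask(scores, keep, neg)
    shifted = masked - Tensor(masked.data.max(axis=axis, keepdims=True))
    weights = exp(shifted) * Tensor(keep.astype(scores.data.dtype))
    total = weights.sum(axis=axis, keepdims=True)
    safe = total + Tensor((total.data == 0).astype(scores.data.dtype))
    return weights / safe
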