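"""Minimal reverse-mode automatic differentiation over numpy arrays.

The message-passing network needs gradients with respect to model
parameters (training), node input embeddings (atom saliency) and per-edge
binary coefficients (adversarial edge selection). A small tape-based
engine covers all three with one mechanism: each operation records its
parents and a backward closure; :meth:`Tensor.backward` runs the tape in
reverse topological order.

Only the primitives the model uses are implemented: broadcasting
arithmetic, matmul, relu/sigmoid/exp/log/sqrt, reductions, row gather and
segment-sum (the scatter/gather pair that implements per-node message
aggregation on a flat edge list).
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        """Accumulate gradients of this (scalar unless ``grad`` given) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
            t.grad = np.zeros_like(t.data)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _const(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _const(-1.0)))

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return mul(self, _const(-1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _const(x) -> Tensor:
    return Tensor(x)


def constant(x) -> Tensor:
    """A tensor that does not require gradients."""
    return Tensor(x, requires_grad=False)


def parameter(x) -> Tensor:
    """A learnable leaf tensor."""
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g, b.data.shape)

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g * b.data, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g * a.data, b.data.shape)

    out._backward = backward
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g / b.data, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(-g * a.data / (b.data**2), b.data.shape)

    out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a.grad += g @ b.data.T
        if b.requires_grad:
            b.grad += a.data.T @ g

    out._backward = backward
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g * mask

    out._backward = backward
    return out


def exp(a: Tensor) -> Tensor:
    value = np.exp(a.data)
    out = Tensor(value, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g * value

    out._backward = backward
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g / a.data

    out._backward = backward
    return out


def sqrt(a: Tensor) -> Tensor:
    value = np.sqrt(a.data)
    out = Tensor(value, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g * 0.5 / value

    out._backward = backward
    return out


def sigmoid(a: Tensor) -> Tensor:
    value = np.where(
        a.data >= 0,
        1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500))),
        np.exp(np.clip(a.data, -500, 500))
        / (1.0 + np.exp(np.clip(a.data, -500, 500))),
    )
    out = Tensor(value, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g * value * (1.0 - value)

    out._backward = backward
    return out


def tensor_sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def backward(g):
        if a.requires_grad:
            if axis is None:
                a.grad += np.broadcast_to(g, a.data.shape)
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                a.grad += np.broadcast_to(ge, a.data.shape)

    out._backward = backward
    return out


def mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tensor_sum(a, axis=axis, keepdims=keepdims), _const(1.0 / n))


def amax(a: Tensor, axis=0) -> Tensor:
    """Max reduction with subgradient routed to the (first) argmax."""
    value = a.data.max(axis=axis)
    out = Tensor(value, parents=(a,))

    def backward(g):
        if a.requires_grad:
            expanded = np.expand_dims(value, axis)
            mask = a.data == expanded
            mask = mask / mask.sum(axis=axis, keepdims=True)
            a.grad += mask * np.expand_dims(g, axis)

    out._backward = backward
    return out


def gather_rows(a: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``a[index]``; backward scatter-adds into the source rows."""
    index = np.asarray(index, dtype=np.int64)
    out = Tensor(a.data[index], parents=(a,))

    def backward(g):
        if a.requires_grad:
            np.add.at(a.grad, index, g)

    out._backward = backward
    return out


def segment_sum(a: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets given by ``segment_ids``."""
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    value = np.zeros((num_segments,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(value, segment_ids, a.data)
    out = Tensor(value, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g[segment_ids]

    out._backward = backward
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a.grad += g.reshape(a.data.shape)

    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis=1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t.grad += piece

    out._backward = backward
    return out


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    out = matmul(x, weight)
    return out if bias is None else add(out, bias)


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Column-wise softmax within each segment of rows.

    Stabilized by subtracting the per-segment maximum (treated as a
    constant, which leaves the gradient of the softmax unchanged).
    Segments with no rows simply produce no weights.
    """
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    seg_max = np.full((num_segments,) + scores.data.shape[1:], -np.inf)
    np.maximum.at(seg_max, segment_ids, scores.data)
    seg_max[~np.isfinite(seg_max)] = 0.0
    shifted = add(scores, constant(-seg_max[segment_ids]))
    z = exp(shifted)
    denom = segment_sum(z, segment_ids, num_segments)
    safe = denom.data == 0
    denom = add(denom, constant(safe.astype(np.float64)))
    return div(z, gather_rows(denom, segment_ids))
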