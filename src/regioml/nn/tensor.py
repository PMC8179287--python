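"""A small reverse-mode automatic-differentiation engine on NumPy arrays.

Provides exactly the primitives the graph networks in this package need:
elementwise arithmetic with broadcasting, matrix multiplication, common
nonlinearities, row gather/concat, and segment reductions for batched
molecular graphs.  Gradients are accumulated into leaf tensors created with
``requires_grad=True``; correctness is checked against finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "relu",
    "softplus",
    "softmax",
    "segment_sum",
    "segment_softmax",
    "cross_entropy_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None) -> None:
        topo, seen = [], set()

        def build(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ------------------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor(-self.data, _parents=(self,), _backward=back)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor(self.data / other.data, _parents=(self, other), _backward=back)

    def __pow__(self, exponent: float):
        def back(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, _parents=(self,), _backward=back)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=back)

    __matmul__ = matmul

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, float(g)))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,), _backward=back)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=back)

    def log(self) -> "Tensor":
        def back(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=back)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor(out_data, _parents=(self,), _backward=back)

    def gather(self, idx) -> "Tensor":
        """Row gather: result[k] = self[idx[k]]; gradient scatter-adds."""
        idx = np.asarray(idx, dtype=np.intp)

        def back(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accum(acc)

        return Tensor(self.data[idx], _parents=(self,), _backward=back)

    def transpose(self) -> "Tensor":
        def back(g):
            if self.requires_grad:
                self._accum(g.T)

        return Tensor(self.data.T, _parents=(self,), _backward=back)

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def reshape(self, *shape) -> "Tensor":
        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=back)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=back,
    )


def relu(t: Tensor) -> Tensor:
    t = as_tensor(t)
    mask = t.data > 0

    def back(g):
        if t.requires_grad:
            t._accum(g * mask)

    return Tensor(t.data * mask, _parents=(t,), _backward=back)


def softplus(t: Tensor) -> Tensor:
    """log(1 + e^x), computed stably; derivative is the logistic sigmoid."""
    t = as_tensor(t)
    out_data = np.logaddexp(0.0, t.data)
    sig = 1.0 / (1.0 + np.exp(-t.data))

    def back(g):
        if t.requires_grad:
            t._accum(g * sig)

    return Tensor(out_data, _parents=(t,), _backward=back)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    # shift by a detached max for stability; softmax is shift invariant
    shift = np.max(t.data, axis=axis, keepdims=True)
    e = (t - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def segment_sum(t: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets given per-row ids."""
    t = as_tensor(t)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + t.shape[1:], dtype=np.float64)
    np.add.at(out_data, segment_ids, t.data)

    def back(g):
        if t.requires_grad:
            t._accum(g[segment_ids])

    return Tensor(out_data, _parents=(t,), _backward=back)


def segment_softmax(t: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Softmax over rows sharing a segment id (per-molecule/per-record)."""
    t = as_tensor(t)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    # detached per-segment max for stability
    seg_max = np.full((num_segments,) + t.shape[1:], -np.inf)
    np.maximum.at(seg_max, segment_ids, t.data)
    e = (t - Tensor(seg_max[segment_ids])).exp()
    denom = segment_sum(e, segment_ids, num_segments)
    return e / denom.gather(segment_ids)


def cross_entropy_logits(logits: Tensor, target_index: int) -> Tensor:
    """-log softmax(logits)[target] for a 1-D logits tensor."""
    p = softmax(logits, axis=0)
    return -(p.gather([target_index]).log().sum())
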