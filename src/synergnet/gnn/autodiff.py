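"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the graph network needs: broadcasting
arithmetic, matmul, relu/exp/log/pow, axis reductions, concatenation, row
gathering, and segment (scatter) sum/max.  Gradients are accumulated by a
topologically ordered backward sweep; correctness is verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather", "segment_sum", "segment_max"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(grad):
            return (
                _unbroadcast(grad, self.shape),
                _unbroadcast(grad, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(grad):
            return (
                _unbroadcast(grad * other.data, self.shape),
                _unbroadcast(grad * self.data, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * self._wrap(other).pow(-1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out_data = np.power(self.data, exponent)

        def backward(grad):
            return (grad * exponent * np.power(self.data, exponent - 1.0),)

        return Tensor._from_op(out_data, (self,), backward)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(grad):
            return (grad @ other.data.T, self.data.T @ grad)

        return Tensor._from_op(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities --------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = self.data * mask

        def backward(grad):
            return (grad * mask,)

        return Tensor._from_op(out_data, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(grad):
            return (grad * out_data,)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(grad):
            return (grad / self.data,)

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autograd driver -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g


# ---------------------------------------------------------------------------
# Free functions
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        return tuple(
            np.take(grad, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor._from_op(out_data, tuple(tensors), backward)


def gather(t: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``t[index]`` (first axis)."""
    index = np.asarray(index, dtype=np.intp)
    out_data = t.data[index]

    def backward(grad):
        out = np.zeros_like(t.data)
        np.add.at(out, index, grad)
        return (out,)

    return Tensor._from_op(out_data, (t,), backward)


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + t.data.shape[1:])
    np.add.at(out_data, segment_ids, t.data)

    def backward(grad):
        return (grad[segment_ids],)

    return Tensor._from_op(out_data, (t,), backward)


def segment_max(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Per-segment element-wise maximum; empty segments yield 0.

    The gradient flows to one argmax row per (segment, column).
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    n_cols = t.data.shape[1]
    out_data = np.zeros((num_segments, n_cols))
    argmax = np.full((num_segments, n_cols), -1, dtype=np.intp)
    order = np.argsort(segment_ids, kind="stable")
    boundaries = np.searchsorted(segment_ids[order], np.arange(num_segments + 1))
    for seg in range(num_segments):
        rows = order[boundaries[seg] : boundaries[seg + 1]]
        if len(rows) == 0:
            continue  # empty segment yields 0
        sub = t.data[rows]
        local = sub.argmax(axis=0)
        argmax[seg] = rows[local]
        out_data[seg] = sub[local, np.arange(n_cols)]

    def backward(grad):
        out = np.zeros_like(t.data)
        cols = np.arange(n_cols)
        for seg in range(num_segments):
            rows = argmax[seg]
            valid = rows >= 0
            np.add.at(out, (rows[valid], cols[valid]), grad[seg, valid])
        return (out,)

    return Tensor._from_op(out_data, (t,), backward)
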