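"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express an embedding layer, a multi-layer
bidirectional LSTM and a feed-forward scorer, and to backpropagate the
triplet max-margin loss: broadcast-aware add/mul, matmul, pointwise
nonlinearities, row gathering (embedding lookup), concatenation, slicing and
hard max.  Everything is float64, which keeps finite-difference gradient
checks tight.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def backward():
            self._accum(_unbroadcast(out.grad, self.data.shape))
            other._accum(_unbroadcast(out.grad, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward():
            self._accum(-out.grad)

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def backward():
            self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward():
            self._accum(out.grad @ other.data.T)
            other._accum(self.data.T @ out.grad)

        out = self._make(out_data, (self, other), backward)
        return out

    # -- nonlinearities --------------------------------------------------

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward():
            self._accum(out.grad * (1.0 - out_data**2))

        out = self._make(out_data, (self,), backward)
        return out

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward():
            self._accum(out.grad * out_data * (1.0 - out_data))

        out = self._make(out_data, (self,), backward)
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward():
            self._accum(out.grad * mask)

        out = self._make(self.data * mask, (self,), backward)
        return out

    # -- shape ops -------------------------------------------------------

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]

        def backward():
            grad = np.zeros_like(self.data)
            np.add.at(grad, key, out.grad)
            self._accum(grad)

        out = self._make(np.array(out_data), (self,), backward)
        return out

    def take_rows(self, indices: Sequence[int]) -> "Tensor":
        """Gather rows (embedding lookup); gradient scatter-adds."""
        idx = np.asarray(indices, dtype=np.intp)
        out_data = self.data[idx]

        def backward():
            grad = np.zeros_like(self.data)
            np.add.at(grad, idx, out.grad)
            self._accum(grad)

        out = self._make(out_data, (self,), backward)
        return out

    def reshape(self, *shape) -> "Tensor":
        old_shape = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward():
            self._accum(out.grad.reshape(old_shape))

        out = self._make(out_data, (self,), backward)
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            grad = out.grad
            if axis is not None and not keepdims:
                grad = np.expand_dims(grad, axis)
            self._accum(np.broadcast_to(grad, self.data.shape).copy())

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self) -> "Tensor":
        """Hard max over all elements; gradient flows to the first argmax."""
        flat_idx = int(np.argmax(self.data))

        def backward():
            grad = np.zeros_like(self.data)
            grad.flat[flat_idx] = out.grad
            self._accum(grad)

        out = self._make(np.array(self.data.flat[flat_idx]), (self,), backward)
        return out

    # -- backward pass ---------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (scalar, unless ``grad`` is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() on a non-scalar requires an explicit gradient")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along ``axis``; gradients are split back."""
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out_data.ndim
            sl[axis] = slice(lo, hi)
            t._accum(out.grad[tuple(sl)])

    out = Tensor._make(out_data, tuple(tensors), backward)
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Stack along a new axis; gradients are unstacked."""
    tensors = list(tensors)
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward():
        for i, t in enumerate(tensors):
            t._accum(np.take(out.grad, i, axis=axis))

    out = Tensor._make(out_data, tuple(tensors), backward)
    return out


def zero_grads(params: Sequence[Tensor]) -> None:
    for p in params:
        p.grad = None
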