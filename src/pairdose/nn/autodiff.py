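"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied
to it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients into every tensor created with ``requires_grad=True``.
The op set is deliberately small — exactly what the encoder networks, the
prediction heads and the graph layers in this package need — and every
backward rule is written against plain numpy so the whole stack runs on one
CPU with no compiled extensions.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concatenate", "relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A numpy array with an attached gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._prev = _prev
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(-g)

        out._backward = backward
        return out

    def __sub__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other) -> "Tensor":
        return Tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __matmul__(self, other: "Tensor") -> "Tensor":
        """Matrix product; the right operand must be 2-D (a weight matrix)."""
        if other.data.ndim != 2:
            raise ValueError("matmul: right operand must be 2-D")
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                k = self.data.shape[-1]
                n = g.shape[-1]
                other._accum(self.data.reshape(-1, k).T @ g.reshape(-1, n))

        out._backward = backward
        return out

    def square(self) -> "Tensor":
        return self * self

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def take_rows(self, idx: np.ndarray) -> "Tensor":
        """Select rows (axis 0) by an integer index array; gradient scatter-adds."""
        idx = np.asarray(idx)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                gd = np.zeros_like(self.data)
                np.add.at(gd, idx, g)
                self._accum(gd)

        out._backward = backward
        return out

    def gather_windows(self, idx2d: np.ndarray) -> "Tensor":
        """For data (B, L, C) and idx2d (P, K), return (B, P, K, C) windows."""
        out = Tensor(self.data[:, idx2d, :], self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                gd = np.zeros_like(self.data)
                np.add.at(gd, (slice(None), idx2d), g)
                self._accum(gd)

        out._backward = backward
        return out

    def pad_axis1(self, before: int, after: int) -> "Tensor":
        """Zero-pad along axis 1 (sequence axis of a (B, L, C) tensor)."""
        width = [(0, 0)] * self.data.ndim
        width[1] = (before, after)
        out = Tensor(np.pad(self.data, width), self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                sl = [slice(None)] * self.data.ndim
                sl[1] = slice(before, before + self.data.shape[1])
                self._accum(g[tuple(sl)])

        out._backward = backward
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis: int | None = None) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis), self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                if axis is None:
                    self._accum(np.full_like(self.data, g))
                else:
                    self._accum(np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        return self.sum() * (1.0 / n)

    def max(self, axis: int) -> "Tensor":
        """Max-reduce one axis; gradient flows to the (first) arg-max entries."""
        arg = np.argmax(self.data, axis=axis)
        out = Tensor(np.max(self.data, axis=axis), self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                gd = np.zeros_like(self.data)
                np.put_along_axis(
                    gd, np.expand_dims(arg, axis), np.expand_dims(g, axis), axis
                )
                self._accum(gd)

        out._backward = backward
        return out

    # -- nonlinearity --------------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = backward
        return out

    # -- autodiff driver -----------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def relu(t: Tensor) -> Tensor:
    return t.relu()


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(
        np.concatenate(datas, axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = backward
    return out
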