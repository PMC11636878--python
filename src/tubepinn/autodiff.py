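"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains physics-informed networks by gradient descent on losses
that themselves contain exact derivatives of the network outputs.  Parameter
gradients are obtained here by taped reverse-mode differentiation; the exact
spatial/case derivatives of network outputs are propagated *forward* as
explicit tensor operations (see :mod:`tubepinn.jets`), so a single layer of
reverse mode over those operations suffices.

Only the primitives the package needs are implemented: elementwise
arithmetic with broadcasting, matmul, exp, sigmoid, powers, reductions,
concatenation, slicing and reshape.  All data is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "sigmoid", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node in the computation tape.

    Parameters with ``requires_grad=True`` accumulate ``.grad`` after
    :meth:`backward`.  Graph construction is skipped entirely for
    subtrees in which no tensor requires gradients.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # make numpy defer mixed ndarray-Tensor arithmetic to our reflected ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(g, self.data.shape)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, self, other)
        if out.requires_grad:
            def _bw(g, a=self, b=other):
                if a.requires_grad or a._backward:
                    a._accumulate(g)
                if b.requires_grad or b._backward:
                    b._accumulate(g)
            out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, self, other)
        if out.requires_grad:
            def _bw(g, a=self, b=other):
                if a.requires_grad or a._backward:
                    a._accumulate(g * b.data)
                if b.requires_grad or b._backward:
                    b._accumulate(g * a.data)
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = _node(self.data ** exponent, self)
        if out.requires_grad:
            def _bw(g, a=self, e=exponent):
                a._accumulate(g * e * a.data ** (e - 1.0))
            out._backward = _bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _node(self.data @ other.data, self, other)
        if out.requires_grad:
            def _bw(g, a=self, b=other):
                if a.requires_grad or a._backward:
                    a._accumulate(g @ b.data.T)
                if b.requires_grad or b._backward:
                    b._accumulate(a.data.T @ g)
            out._backward = _bw
        return out

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # -- transcendental ----------------------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = _node(val, self)
        if out.requires_grad:
            def _bw(g, a=self, v=val):
                a._accumulate(g * v)
            out._backward = _bw
        return out

    # -- reductions and shaping --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), self)
        if out.requires_grad:
            shape = self.data.shape
            def _bw(g, a=self, axis=axis, keepdims=keepdims, shape=shape):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, shape).copy())
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), self)
        if out.requires_grad:
            orig = self.data.shape
            def _bw(g, a=self, orig=orig):
                a._accumulate(g.reshape(orig))
            out._backward = _bw
        return out

    def __getitem__(self, key):
        out = _node(self.data[key], self)
        if out.requires_grad:
            def _bw(g, a=self, key=key):
                full = np.zeros_like(a.data)
                np.add.at(full, key, g)
                a._accumulate(full)
            out._backward = _bw
        return out

    def item(self) -> float:
        return float(self.data)


def _node(data: np.ndarray, *parents: Tensor) -> Tensor:
    out = Tensor(data)
    live = tuple(p for p in parents
                 if p.requires_grad or p._backward is not None or p._prev)
    if live:
        out.requires_grad = True
        out._prev = live
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), *tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def _bw(g, ts=tensors, splits=splits, axis=axis):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._backward:
                    t._accumulate(piece)
        out._backward = _bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    # numerically stable logistic
    val = np.where(x.data >= 0,
                   1.0 / (1.0 + np.exp(-np.abs(x.data))),
                   np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))
    out = _node(val, x)
    if out.requires_grad:
        def _bw(g, a=x, v=val):
            a._accumulate(g * v * (1.0 - v))
        out._backward = _bw
    return out
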