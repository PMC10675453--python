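"""Reverse-mode autodiff core: a Tensor wrapping a float64 ndarray.

Graphs are built eagerly by the functions in :mod:`cowave.nn.ops`; calling
:meth:`Tensor.backward` on a scalar loss topologically sorts the graph and
accumulates gradients into every parameter that requires them. Tensors that
do not require gradients record no graph, so inference is allocation-light.
"""

from __future__ import annotations

from typing import Callable, Optional, Tuple

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Tuple["Tensor", ...] = ()

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def size(self) -> int:
        return self.data.size

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: recurrent graphs can be thousands deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def from_op(data: np.ndarray, parents: Tuple[Tensor, ...], backward) -> Tensor:
    """Build a graph node; drops the graph entirely when no parent needs grads."""
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def accumulate(t: Tensor, g: np.ndarray) -> None:
    """Lazily allocate gradient buffers; copies on first write (g may be a view)."""
    if t.requires_grad:
        if t.grad is None:
            t.grad = np.array(g, dtype=np.float64)
            if t.grad.shape != t.data.shape:  # scalar broadcast (e.g. mean upstream)
                t.grad = np.broadcast_to(t.grad, t.data.shape).copy()
        else:
            t.grad += g


def unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to *shape*."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g
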