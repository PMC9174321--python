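"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine covers exactly the operations needed by the segmentation and
multiple-instance networks in this package: 2-D convolution (dense and
depthwise), batch normalization, pooling/upsampling, pointwise
nonlinearities, and the scalar bag-level operations (signed p-norm root,
piecewise probability transform, binary cross-entropy).  Everything is
float32 and single-threaded-deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def make(data: np.ndarray, parents: tuple, backward) -> Tensor:
    """Build a graph node; drops the tape when inside ``no_grad``."""
    track = _grad_enabled and any(p.requires_grad or p._parents for p in parents)
    out = Tensor(data)
    if track:
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out
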