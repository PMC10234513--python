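"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the sequence models need: broadcasting
arithmetic, batched matrix products, reshapes/transposes, reductions,
embedding lookup, numerically stable (log-)softmax, masked fill, and layer
normalisation, together with an Adam optimiser.  Gradients are accumulated by
a topological backward sweep over the recorded computation graph.

All arrays are float64; the engine is designed for correctness and
desk-scale model sizes, not GPU throughput.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # collapse leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # -- graph plumbing -----------------------------------------------------

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

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
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
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
            out.requires_grad = True
        return out

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other).power(-1.0)

    def power(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return self._make(out_data, (self,), backward)

    def matmul(self, other: "Tensor"):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accum(_unbroadcast(ga, self.data.shape))
            other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            self._accum(g.reshape(orig))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        out_data = np.transpose(self.data, axes)
        inv = np.argsort(axes)

        def backward(g):
            self._accum(np.transpose(g, inv))

        return self._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def backward(g):
            self._accum(np.swapaxes(g, a, b))

        return self._make(out_data, (self,), backward)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -----------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax with analytic Jacobian-vector product."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        soft = np.exp(out_data)

        def backward(g):
            self._accum(g - soft * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), backward)

    # -- structured ops -----------------------------------------------------

    def embedding(self, indices: np.ndarray):
        """Row lookup: self is a (V, d) table, indices an integer array."""
        idx = np.asarray(indices)
        out_data = self.data[idx]

        def backward(g):
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, idx, g)

        return self._make(out_data, (self,), backward)

    def masked_fill(self, mask: np.ndarray, value: float):
        """Set entries where `mask` is True to `value` (no gradient there)."""
        mask = np.broadcast_to(np.asarray(mask, dtype=bool), self.data.shape)
        out_data = np.where(mask, value, self.data)

        def backward(g):
            self._accum(np.where(mask, 0.0, g))

        return self._make(out_data, (self,), backward)

    def take_along_last(self, indices: np.ndarray):
        """Gather one entry per row along the last axis (for cross-entropy)."""
        idx = np.asarray(indices)
        expanded = np.expand_dims(idx, -1)
        out_data = np.take_along_axis(self.data, expanded, axis=-1)[..., 0]

        def backward(g):
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.put_along_axis(
                self.grad,
                expanded,
                np.take_along_axis(self.grad, expanded, axis=-1)
                + np.expand_dims(g, -1),
                axis=-1,
            )

        return self._make(out_data, (self,), backward)

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-5):
        """Normalise over the last axis, then scale and shift."""
        mu = self.mean(axis=-1, keepdims=True)
        centred = self - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        inv = (var + eps).power(-0.5)
        return centred * inv * gain + bias

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
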