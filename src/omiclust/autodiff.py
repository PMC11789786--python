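"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training objective couples two-layer graph convolutions, tanh decoders and
two NT-Xent style contrastive terms; everything it needs reduces to a small op
set (matmul, elementwise arithmetic, tanh/exp/log/power, axis reductions,
transpose and a lower-clip). :class:`Tensor` builds the computation graph
dynamically; :meth:`Tensor.backward` accumulates gradients by reverse
topological sweep. Shapes are plain numpy broadcasting; gradients of broadcast
operands are summed back to the operand's shape.

Only what the model uses is implemented — this is not a general DL framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    grad = np.asarray(grad, dtype=float)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    value : array-like
        Numeric payload, stored as float64.
    parents : tuple of Tensor
        Upstream nodes this value was computed from.
    grad_fns : tuple of callables
        One per parent; maps the output gradient to that parent's gradient
        contribution.
    """

    __slots__ = ("value", "parents", "grad_fns", "grad")

    def __init__(self, value, parents=(), grad_fns=()):
        self.value = np.asarray(value, dtype=float)
        self.parents = tuple(parents)
        self.grad_fns = tuple(grad_fns)
        self.grad = None

    # -- graph traversal ----------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this (scalar) node, filling ``.grad`` fields."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        for node in order:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            g = node.grad
            for parent, fn in zip(node.parents, node.grad_fns):
                parent.grad = parent.grad + _unbroadcast(fn(g), parent.value.shape)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(self.value + other.value, (self, other),
                      (lambda g: g, lambda g: g))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, (self,), (lambda g: -g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self.value, other.value
        return Tensor(a * b, (self, other),
                      (lambda g: g * b, lambda g: g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self.value, other.value
        return Tensor(a / b, (self, other),
                      (lambda g: g / b, lambda g: -g * a / (b * b)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.value, other.value
        return Tensor(a @ b, (self, other),
                      (lambda g: g @ b.T, lambda g: a.T @ g))

    def __pow__(self, p: float):
        a = self.value
        return Tensor(a ** p, (self,), (lambda g: g * p * a ** (p - 1),))

    # -- nonlinearities -----------------------------------------------------

    def tanh(self):
        out = np.tanh(self.value)
        return Tensor(out, (self,), (lambda g: g * (1.0 - out * out),))

    def exp(self):
        out = np.exp(self.value)
        return Tensor(out, (self,), (lambda g: g * out,))

    def log(self):
        a = self.value
        return Tensor(np.log(a), (self,), (lambda g: g / a,))

    def clip_min(self, low: float):
        """Elementwise max(x, low); gradient is blocked where clipped."""
        a = self.value
        mask = (a >= low).astype(float)
        return Tensor(np.maximum(a, low), (self,), (lambda g: g * mask,))

    # -- reductions / reshaping --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self.value

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, a.shape)
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, a.shape)

        return Tensor(a.sum(axis=axis, keepdims=keepdims), (self,), (grad_fn,))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    @property
    def T(self):
        return Tensor(self.value.T, (self,), (lambda g: g.T,))

    @property
    def shape(self):
        return self.value.shape

    def item(self) -> float:
        return float(self.value)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape})"


def as_tensor(x) -> Tensor:
    """Wrap `x` as a (leaf) Tensor; Tensors pass through unchanged."""
    return x if isinstance(x, Tensor) else Tensor(x)


class Adam:
    """Adam optimizer over leaf Tensors (reads ``.grad``, updates ``.value``)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            mhat = m / (1.0 - self.b1 ** self.t)
            vhat = v / (1.0 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
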