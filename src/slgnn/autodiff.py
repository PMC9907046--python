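"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model is small enough (dense parameter tables, a few hundred graph
operations per training step) that a compact tape-based engine is all that
is needed: :class:`Tensor` wraps a float64 ``ndarray``, records the
operations applied to it, and :meth:`Tensor.backward` accumulates exact
gradients by walking the tape in reverse topological order.

Only the primitives the model needs are implemented: broadcasting
arithmetic, matmul, reductions, elementwise nonlinearities, row gather
(``take``), and its scatter-add adjoint (``segment_sum``), which together
express every message-passing and attention step in the network.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "astensor", "segment_sum", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A float64 array node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- introspection ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff ---------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node; ``grad`` defaults to ones."""
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that does not require grad")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = astensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g):
            self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-astensor(other))

    def __rsub__(self, other) -> "Tensor":
        return astensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = astensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = astensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    def __rtruediv__(self, other) -> "Tensor":
        return astensor(other) / self

    def __matmul__(self, other) -> "Tensor":
        other = astensor(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T if other.ndim == 2 else np.outer(g, other.data))
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- elementwise ------------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def log(self) -> "Tensor":
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bw)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def abs(self) -> "Tensor":
        def bw(g):
            self._accumulate(g * np.sign(self.data))

        return Tensor(np.abs(self.data), _parents=(self,), _backward=bw)

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        out_data = np.where(self.data >= 0,
                            1.0 / (1.0 + np.exp(-np.abs(self.data))),
                            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))))

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def leaky_relu(self, negative_slope: float = 0.2) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, negative_slope)

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bw)

    def maximum(self, value: float) -> "Tensor":
        """Elementwise max with a constant; subgradient 0 below the cut."""
        mask = (self.data >= value).astype(np.float64)

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(np.maximum(self.data, value), _parents=(self,), _backward=bw)

    # -- shape ------------------------------------------------------------
    def reshape(self, shape: Sequence[int]) -> "Tensor":
        def bw(g):
            self._accumulate(g.reshape(self.shape))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bw)

    @property
    def T(self) -> "Tensor":
        def bw(g):
            self._accumulate(g.T)

        return Tensor(self.data.T, _parents=(self,), _backward=bw)

    # -- gather / scatter -------------------------------------------------
    def take(self, indices: np.ndarray) -> "Tensor":
        """Gather rows (axis 0)."""
        indices = np.asarray(indices, dtype=np.intp)

        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, indices, g)
            self._accumulate(acc)

        return Tensor(self.data[indices], _parents=(self,), _backward=bw)


def astensor(x) -> Tensor:
    """Promote a scalar or ndarray to a constant :class:`Tensor`."""
    return x if isinstance(x, Tensor) else Tensor(x)


def segment_sum(values: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``values`` into ``num_segments`` buckets given by ``segment_ids``."""
    values = astensor(values)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_shape = (num_segments,) + values.shape[1:]
    out_data = np.zeros(out_shape, dtype=np.float64)
    np.add.at(out_data, segment_ids, values.data)

    def bw(g):
        values._accumulate(g[segment_ids])

    return Tensor(out_data, _parents=(values,), _backward=bw)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=bw)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 0.002,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params]
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
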