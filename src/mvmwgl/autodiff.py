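"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine providing exactly the operations the
message-passing layers and training heads need: broadcasting arithmetic,
(batched) matrix products, ReLU/LeakyReLU, exp/log/power, reductions, reshape,
row gather/indexing, and an Adam optimizer. Gradients are checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast up from ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      _parents=parents if req else (), _backward=backward if req else None)

    def backward(self) -> None:
        """Accumulate gradients of a scalar output into every parameter."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents supported")

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return self._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out = np.matmul(self.data, other.data)

        def backward(g):
            self._accumulate(
                _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape)
            )
            other._accumulate(
                _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape)
            )

        return self._make(out, (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return self._make(np.where(mask, self.data, 0.0), (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * np.where(mask, 1.0, slope))

        return self._make(np.where(mask, self.data, slope * self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes only where x > lo."""
        mask = self.data > lo

        def backward(g):
            self._accumulate(g * mask)

        return self._make(np.maximum(self.data, lo), (self,), backward)

    # -- reductions & shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            self._accumulate(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            self._accumulate(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), backward)

    def take_rows(self, indices: np.ndarray):
        """Select rows (leading axis) by integer index; scatter-add backward."""
        indices = np.asarray(indices, dtype=int)

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, indices, g)
            self._accumulate(grad)

        return self._make(self.data[indices], (self,), backward)

    def gather(self, indices: np.ndarray):
        """Per-row element pick: out[i] = x[i, indices[i]] for a 2-D tensor."""
        indices = np.asarray(indices, dtype=int)
        rows = np.arange(self.data.shape[0])

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, (rows, indices), g)
            self._accumulate(grad)

        return self._make(self.data[rows, indices], (self,), backward)

    def detached_max(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Max of the data, outside the graph (for stable softmax shifts)."""
        return self.data.max(axis=axis, keepdims=keepdims)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=float), requires_grad=True)


class Adam:
    """Adam with the standard moment defaults (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1 ** self.t)
            v_hat = self.v[i] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
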