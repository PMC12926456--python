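"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the graph layers need: broadcast
arithmetic, dense and sparse-constant matrix products, pointwise
nonlinearities, row gather/scatter (for edge-wise attention and graph
unpooling), concatenation, reductions, and a fused softmax cross-entropy.
Gradients are accumulated through a topological sweep; all math is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "cross_entropy", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
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
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(grad):
            if self.requires_grad:
                self._accum(_unbroadcast(grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad):
            if self.requires_grad:
                self._accum(-grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(grad):
            if self.requires_grad:
                self._accum(_unbroadcast(grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(grad * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def backward(grad):
            if self.requires_grad:
                self._accum(_unbroadcast(grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-grad * self.data / (other.data**2), other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._coerce(other)

        def backward(grad):
            if self.requires_grad:
                self._accum(grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ grad)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    def spmm(self, sparse_const):
        """Left-multiply by a constant scipy sparse matrix: ``S @ self``."""

        def backward(grad):
            if self.requires_grad:
                self._accum(np.asarray(sparse_const.T @ grad))

        return Tensor._make(np.asarray(sparse_const @ self.data), (self,), backward)

    # -- pointwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad):
            if self.requires_grad:
                self._accum(grad * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(grad):
            if self.requires_grad:
                self._accum(grad / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad):
            if self.requires_grad:
                self._accum(grad * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        neg = self.data < 0
        out_data = np.where(neg, alpha * np.expm1(self.data), self.data)

        def backward(grad):
            if self.requires_grad:
                self._accum(grad * np.where(neg, out_data + alpha, 1.0))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(grad):
            if self.requires_grad:
                self._accum(grad * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)

        def backward(grad):
            if self.requires_grad:
                self._accum(grad * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(grad):
            if self.requires_grad:
                self._accum(grad * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    # -- shape / index -----------------------------------------------------
    def gather_rows(self, index: np.ndarray):
        """Select rows: out[k] = self[index[k]]."""
        index = np.asarray(index, dtype=np.int64)

        def backward(grad):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, index, grad)
                self._accum(g)

        return Tensor._make(self.data[index], (self,), backward)

    def scatter_rows(self, index: np.ndarray, n_rows: int):
        """Sum rows into an (n_rows, ...) output: out[index[k]] += self[k].

        Serves both as segment-sum (attention aggregation) and graph
        unpooling (when ``index`` is injective, rows are placed, rest zero).
        """
        index = np.asarray(index, dtype=np.int64)
        out_data = np.zeros((n_rows,) + self.data.shape[1:])
        np.add.at(out_data, index, self.data)

        def backward(grad):
            if self.requires_grad:
                self._accum(grad[index])

        return Tensor._make(out_data, (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        def backward(grad):
            if self.requires_grad:
                g = np.asarray(grad)
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(grad):
            if self.requires_grad:
                self._accum(np.full(self.shape, float(grad) / n))

        return Tensor._make(self.data.mean(), (self,), backward)

    def reshape(self, *shape):
        old = self.shape

        def backward(grad):
            if self.requires_grad:
                self._accum(grad.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    # -- autodiff driver ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(grad[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-row softmax cross-entropy against integer labels."""
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-300))

    def backward(grad):
        if logits.requires_grad:
            g = probs.copy()
            g[np.arange(n), labels] -= 1.0
            logits._accum(float(grad) * g / n)

    return Tensor._make(loss, (logits,), backward)


class Adam:
    """Adaptive-moment gradient descent (bias-corrected first/second moments)."""

    def __init__(self, params: list[Parameter], lr: float = 0.01,
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
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
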