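"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to train the attention-based and GraphSAGE-based
feature extractors: broadcasting elementwise arithmetic, 2-D matrix
products, the activations the models use, reductions, reshape/concat and
integer-array gathers, plus an Adam optimiser.  Gradients are accumulated
by topological-order backpropagation from a scalar loss.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to the reflected operators on ndarray <op> Tensor
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=float)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        def backward(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))
        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)
        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))
        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(_unbroadcast(-g * self.data / other.data ** 2, other.shape))
        return self._node(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        if self.data.ndim != 2 or other.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)
        return self._node(self.data @ other.data, (self, other), backward)

    def __rmatmul__(self, other):
        return self._lift(other) @ self

    # -- activations -------------------------------------------------------

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        def backward(g):
            self._accumulate(g * y * (1.0 - y))
        return self._node(y, (self,), backward)

    def tanh(self):
        y = np.tanh(self.data)
        def backward(g):
            self._accumulate(g * (1.0 - y ** 2))
        return self._node(y, (self,), backward)

    def elu(self, alpha: float = 1.0):
        y = np.where(self.data > 0, self.data, alpha * np.expm1(self.data))
        def backward(g):
            self._accumulate(g * np.where(self.data > 0, 1.0, y + alpha))
        return self._node(y, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        y = np.where(self.data > 0, self.data, slope * self.data)
        def backward(g):
            self._accumulate(g * np.where(self.data > 0, 1.0, slope))
        return self._node(y, (self,), backward)

    def relu(self):
        return self.leaky_relu(0.0)

    def exp(self):
        y = np.exp(np.clip(self.data, -60, 60))
        def backward(g):
            self._accumulate(g * y)
        return self._node(y, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)
        return self._node(np.log(self.data), (self,), backward)

    # -- reductions and shaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())
        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        old = self.shape
        def backward(g):
            self._accumulate(g.reshape(old))
        return self._node(self.data.reshape(*shape), (self,), backward)

    def take(self, indices, axis: int = 0):
        """Gather rows (or slices along ``axis``) by an integer index array."""
        indices = np.asarray(indices)
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (slice(None),) * axis + (indices,), g)
            self._accumulate(full)
        return self._node(np.take(self.data, indices, axis=axis), (self,), backward)

    @staticmethod
    def einsum(spec_fwd: str, spec_ga: str, spec_gb: str,
               a: "Tensor", b: "Tensor") -> "Tensor":
        """Two-operand einsum with caller-supplied gradient contractions.

        ``spec_ga`` contracts (output-grad, b) to a's gradient; ``spec_gb``
        contracts (a, output-grad) to b's gradient.
        """
        a, b = Tensor._lift(a), Tensor._lift(b)
        def backward(g):
            a._accumulate(np.einsum(spec_ga, g, b.data))
            b._accumulate(np.einsum(spec_gb, a.data, g))
        return Tensor._node(np.einsum(spec_fwd, a.data, b.data), (a, b), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        def backward(g):
            start = 0
            for t, size in zip(tensors, sizes):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + size)
                t._accumulate(g[tuple(sl)])
                start += size
        return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis),
                            tuple(tensors), backward)


def masked_softmax(scores: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax along ``axis`` over entries where ``mask`` is true.

    Fully-masked slices return all-zero weights rather than NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    shift = scores.data.max(axis=axis, keepdims=True)  # constant shift: softmax-invariant
    e = (scores - shift).exp() * mask.astype(float)
    total = e.sum(axis=axis, keepdims=True)
    return e / _safe_total(total)


def _safe_total(total: Tensor) -> Tensor:
    # avoid division by zero on fully masked rows; those rows are already 0
    bump = (total.data == 0).astype(float)
    return total + Tensor(bump)


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
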