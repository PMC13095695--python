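"""Minimal reverse-mode automatic differentiation over numpy arrays.

The generative pipeline trains two small neural networks (a
discretization-agnostic per-vertex feature extractor and a spiral-convolution
variational autoencoder). Both are expressed as computation graphs over this
module's :class:`Tensor`, which records parents and a backward closure per
operation and accumulates gradients by reverse topological traversal.

Only the operations those models need are implemented: broadcast arithmetic,
dense/sparse matrix products, row gathering (with scatter-add adjoint),
reductions, elementwise nonlinearities, and a small-matrix inverse. Constant
inputs (eigenbases, mass matrices, spiral index tables) enter the graph as
plain numpy arrays or as non-differentiable Tensors.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "Parameter", "Adam", "concat", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        a, b = self, self._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, self._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, self._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / b.data**2, b.shape))

        return self._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        a, b = self, self._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return self._make(a.data[idx], (a,), bwd)

    # -- shape ops -------------------------------------------------------

    def reshape(self, *shape):
        a = self
        orig = a.shape
        return self._make(a.data.reshape(*shape), (a,), lambda g: a._accum(g.reshape(orig)))

    @property
    def T(self):
        a = self
        return self._make(a.data.T, (a,), lambda g: a._accum(g.T))

    def take_rows(self, index: np.ndarray) -> "Tensor":
        """Gather rows by an integer array (any shape); adjoint scatter-adds."""
        a = self
        index = np.asarray(index)

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, index.ravel(), g.reshape(-1, *a.shape[1:]))
            a._accum(full)

        return self._make(a.data[index], (a,), bwd)

    # -- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- elementwise -----------------------------------------------------

    def _unary(self, fval, fgrad):
        a = self
        val = fval(a.data)
        return self._make(val, (a,), lambda g: a._accum(g * fgrad(a.data, val)))

    def exp(self):
        return self._unary(np.exp, lambda x, v: v)

    def log(self):
        return self._unary(np.log, lambda x, v: 1.0 / x)

    def sqrt(self):
        return self._unary(np.sqrt, lambda x, v: 0.5 / v)

    def square(self):
        return self._unary(np.square, lambda x, v: 2.0 * x)

    def abs(self):
        return self._unary(np.abs, lambda x, v: np.sign(x))

    def relu(self):
        return self._unary(lambda x: np.maximum(x, 0.0), lambda x, v: (x > 0).astype(np.float64))

    def elu(self, alpha: float = 1.0):
        return self._unary(
            lambda x: np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0))),
            lambda x, v: np.where(x > 0, 1.0, v + alpha),
        )

    def tanh(self):
        return self._unary(np.tanh, lambda x, v: 1.0 - v**2)

    def softplus(self):
        # log(1+e^x), numerically stable for large |x|
        return self._unary(
            lambda x: np.logaddexp(0.0, x),
            lambda x, v: 1.0 / (1.0 + np.exp(-x)),
        )

    def arccos(self, eps: float = 1e-9):
        a = self

        def bwd(g):
            x = np.clip(a.data, -1.0 + eps, 1.0 - eps)
            a._accum(-g / np.sqrt(1.0 - x**2))

        return self._make(np.arccos(np.clip(a.data, -1.0, 1.0)), (a,), bwd)

    # -- linear algebra --------------------------------------------------

    def inv(self):
        """Matrix inverse of a small square matrix; d(A^-1) = -A^-1 dA A^-1."""
        a = self
        val = np.linalg.inv(a.data)
        return self._make(val, (a,), lambda g: a._accum(-val.T @ g @ val.T))

    def spmm(self, sparse: sp.spmatrix) -> "Tensor":
        """Left-multiply by a constant sparse matrix: returns sparse @ self."""
        a = self
        mat = sparse.tocsr()
        return self._make(mat @ a.data, (a,), lambda g: a._accum(mat.T @ g))

    # -- autograd driver -------------------------------------------------

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable Tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = bwd
    return out


class no_grad:
    """Context that detaches new Parameters' graphs — placeholder for API parity.

    Forward passes built from plain Tensors without requires_grad already skip
    graph construction, so evaluation code simply avoids Parameters' gradients
    by not calling backward; this context exists for readability at call sites.
    """

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
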