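"""Minimal vectorized reverse-mode autodiff over numpy arrays.

Just enough machinery for a small graph neural network trained on the CPU:
dense linear algebra, pointwise nonlinearities, row gathering and segment
reductions (the scatter/gather primitives of message passing).  Gradients are
accumulated by topological-order backpropagation, micrograd-style but on
whole arrays.
"""

from __future__ import annotations

import numpy as np

# float32 keeps training fast on CPU; gradient-checking code may switch to
# float64 for tight finite-difference agreement
DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient down to the shape it was broadcast from."""
    if grad.shape == shape:
        return grad
    # remove leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    # ---- graph machinery -------------------------------------------------
    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None \
            else np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)
        out = Tensor(self.data + other.data, (self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)
        out = Tensor(self.data * other.data, (self, other))
        out._backward = lambda g: (self._accum(g * other.data), other._accum(g * self.data))
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other, requires_grad=False) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other, requires_grad=False)
        out = Tensor(self.data / other.data, (self, other))

        def back(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data ** 2)

        out._backward = back
        return out

    def matmul(self, other):
        out = Tensor(self.data @ other.data, (self, other))

        def back(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = back
        return out

    __matmul__ = matmul

    # ---- pointwise -------------------------------------------------------
    def exp(self):
        val = np.exp(self.data)  # captured by value: no self-referential cycle
        out = Tensor(val, (self,))
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def leaky_relu(self, alpha: float = 0.2):
        factor = np.where(self.data > 0, 1.0, alpha)
        out = Tensor(self.data * factor, (self,))
        out._backward = lambda g: self._accum(g * factor)
        return out

    # ---- shaping ---------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out._backward = back
    return out


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Row indexing t[idx]; gradient scatters back with accumulation."""
    idx = np.asarray(idx, dtype=int)
    out = Tensor(t.data[idx], (t,))

    def back(g):
        acc = np.zeros_like(t.data)
        np.add.at(acc, idx, g)
        t._accum(acc)

    out._backward = back
    return out


def segment_sum(t: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of t into n_segments bins given by seg (same length as rows)."""
    seg = np.asarray(seg, dtype=int)
    data = np.zeros((n_segments,) + t.data.shape[1:])
    np.add.at(data, seg, t.data)
    out = Tensor(data, (t,))
    out._backward = lambda g: t._accum(g[seg])
    return out


def segment_max(t: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Per-segment maximum; the gradient flows to one argmax row per segment."""
    seg = np.asarray(seg, dtype=int)
    data = np.full((n_segments,) + t.data.shape[1:], -np.inf)
    np.maximum.at(data, seg, t.data)
    # one winning row per (segment, column): the first row attaining the max
    n_rows = t.data.shape[0]
    cand = t.data == data[seg]
    ridx = np.where(cand, np.arange(n_rows).reshape((-1,) + (1,) * (t.data.ndim - 1)), n_rows)
    first = np.full(data.shape, n_rows)
    np.minimum.at(first, seg, ridx)
    winners = cand & (ridx == first[seg])
    out = Tensor(data, (t,))

    def back(g):
        t._accum(np.where(winners, g[seg], 0.0))

    out._backward = back
    return out


def segment_softmax(logits: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Softmax within each segment (stabilized by a detached per-segment max)."""
    seg = np.asarray(seg, dtype=int)
    m = np.full((n_segments,) + logits.data.shape[1:], -np.inf)
    np.maximum.at(m, seg, logits.data)
    shifted = logits - Tensor(m[seg], requires_grad=False)
    e = shifted.exp()
    denom = segment_sum(e, seg, n_segments)
    return e / gather_rows(denom, seg)


def sparse_apply(S, t: Tensor, ST) -> Tensor:
    """y = S @ t for a sparse matrix S with precomputed transpose ST.

    One primitive covers gather (S = row-selection), scatter-sum (S = the
    transpose of a selection) and pooling (S = graph-membership indicator);
    the backward pass is ST @ grad.
    """
    out = Tensor(S @ t.data, (t,))
    out._backward = lambda g: t._accum(ST @ g)
    return out


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
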