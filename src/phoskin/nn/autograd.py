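"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a transformer encoder: broadcasting arithmetic,
batched matmul, fused softmax / log-softmax / layer-norm, embedding lookup,
reductions, reshapes and gathers. Everything is float64; gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` via a
topological sort of the tape.
"""
from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray

#: float32 is the training default; switch to float64 for gradient checks
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be numpy float32 or float64")
    DTYPE = dtype


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from size 1
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[Array], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._grad_borrowed = False

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: Array) -> None:
        # first contribution borrows the incoming buffer; later ones
        # allocate a fresh sum so a buffer shared between siblings is
        # never mutated in place
        if self.grad is None:
            self.grad = g
            self._grad_borrowed = True
        elif self._grad_borrowed:
            self.grad = self.grad + g
            self._grad_borrowed = False
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
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
        self._grad_borrowed = False
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None
        self._grad_borrowed = False

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- construction of result nodes ------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _node(self, data: Array, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        live = tuple(p for p in parents if p.requires_grad or p._parents)
        if live:
            out.requires_grad = True
            out._parents = live
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g: Array) -> None:
            if a.requires_grad or a._parents:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad or b._parents:
                b._accumulate(_unbroadcast(g, b.shape))

        return self._node(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g: Array) -> None:
            if a.requires_grad or a._parents:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad or b._parents:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._node(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        a = self

        def backward(g: Array) -> None:
            a._accumulate(g * exponent * np.power(a.data, exponent - 1.0))

        return self._node(np.power(a.data, exponent), (a,), backward)

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)

        def backward(g: Array) -> None:
            a._accumulate(g * out_data)

        return self._node(out_data, (a,), backward)

    def log(self) -> "Tensor":
        a = self

        def backward(g: Array) -> None:
            a._accumulate(g / a.data)

        return self._node(np.log(a.data), (a,), backward)

    def tanh(self) -> "Tensor":
        a = self
        out_data = np.tanh(a.data)

        def backward(g: Array) -> None:
            a._accumulate(g * (1.0 - out_data**2))

        return self._node(out_data, (a,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        a, b = self, other

        def backward(g: Array) -> None:
            if a.requires_grad or a._parents:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad or b._parents:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.shape))

        return self._node(np.matmul(a.data, b.data), (a, b), backward)

    __matmul__ = matmul

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape: int) -> "Tensor":
        a = self
        old = a.shape

        def backward(g: Array) -> None:
            a._accumulate(g.reshape(old))

        return self._node(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes: int) -> "Tensor":
        a = self
        inverse = np.argsort(axes)

        def backward(g: Array) -> None:
            a._accumulate(g.transpose(inverse))

        return self._node(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, index) -> "Tensor":
        a = self
        parts = index if isinstance(index, tuple) else (index,)
        basic = all(isinstance(p, (int, np.integer, slice, type(Ellipsis))) for p in parts)

        def backward(g: Array) -> None:
            full = np.zeros_like(a.data)
            if basic:  # basic indexing selects each element at most once
                full[index] += g
            else:
                np.add.at(full, index, g)
            a._accumulate(full)

        return self._node(a.data[index], (a,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def backward(g: Array) -> None:
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.shape).copy())

        return self._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# -- fused ops -------------------------------------------------------------
def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g: Array) -> None:
        gx = s * (g - (g * s).sum(axis=axis, keepdims=True))
        x._accumulate(gx)

    return x._node(s, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    soft = np.exp(out_data)

    def backward(g: Array) -> None:
        gx = g - soft * g.sum(axis=axis, keepdims=True)
        x._accumulate(gx)

    return x._node(out_data, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data

    def backward(g: Array) -> None:
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.shape))
        if x.requires_grad or x._parents:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (dxhat - m1 - xhat * m2))

    return x._node(out_data, (x, gamma, beta), backward)


def embedding(table: Tensor, ids: Array) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add gradient.

    For small tables the scatter is done as a one-hot matmul, which is
    much faster than ``np.add.at`` over many duplicate indices.
    """
    ids = np.asarray(ids)
    n_rows = table.data.shape[0]

    def backward(g: Array) -> None:
        if n_rows <= 64 and ids.size > 4 * n_rows:
            onehot = np.zeros((ids.size, n_rows), dtype=table.data.dtype)
            onehot[np.arange(ids.size), ids.ravel()] = 1.0
            full = onehot.T @ g.reshape(ids.size, -1)
        else:
            full = np.zeros_like(table.data)
            np.add.at(full, ids, g)
        table._accumulate(full)

    return table._node(table.data[ids], (table,), backward)


def scaled_dot_attention(
    q: Tensor, k: Tensor, v: Tensor, bias: Array, scale: float
) -> tuple[Tensor, Array]:
    """Fused softmax(q·kᵀ·scale + bias)·v with a hand-written backward.

    ``q``/``k``/``v``: (..., T, dh); ``bias``: additive mask broadcastable
    to the score shape. Returns the context tensor and the (detached)
    attention weights.
    """
    scores = np.matmul(q.data, np.swapaxes(k.data, -1, -2))
    scores *= scale
    scores += bias
    scores -= scores.max(axis=-1, keepdims=True)
    np.exp(scores, out=scores)
    scores /= scores.sum(axis=-1, keepdims=True)
    attn = scores  # (..., T, T)
    out_data = np.matmul(attn, v.data)

    def backward(g: Array) -> None:
        if v.requires_grad or v._parents:
            v._accumulate(np.matmul(np.swapaxes(attn, -1, -2), g))
        ga = np.matmul(g, np.swapaxes(v.data, -1, -2))
        gs = attn * (ga - (ga * attn).sum(axis=-1, keepdims=True))
        gs *= scale
        if q.requires_grad or q._parents:
            q._accumulate(np.matmul(gs, k.data))
        if k.requires_grad or k._parents:
            k._accumulate(np.matmul(np.swapaxes(gs, -1, -2), q.data))

    return q._node(out_data, (q, k, v), backward), attn


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(x: Tensor) -> Tensor:
    """Gaussian-error linear unit (tanh approximation)."""
    u = x.data
    u2 = u * u
    t = np.tanh(_GELU_C * u * (1.0 + 0.044715 * u2))
    out_data = 0.5 * u * (1.0 + t)

    def backward(g: Array) -> None:
        dinner = _GELU_C * (1.0 + 0.134145 * u2)
        grad = 0.5 * (1.0 + t) + 0.5 * u * (1.0 - t * t) * dinner
        grad *= g
        x._accumulate(grad)

    return x._node(out_data, (x,), backward)


def clip_global_norm(params: Iterable[Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad.astype(np.float64) ** 2).sum()) for p in params)))
    if total > max_norm > 0:
        scale = max_norm / total
        for p in params:
            if p._grad_borrowed:
                p.grad = p.grad * scale
                p._grad_borrowed = False
            else:
                p.grad *= scale
    return total


class AdamW:
    """Decoupled-weight-decay Adam (Loshchilov & Hutter)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)
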