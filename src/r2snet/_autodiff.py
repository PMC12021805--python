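"""Minimal reverse-mode automatic differentiation over numpy arrays.

The graph-transformer in :mod:`r2snet.model` needs gradients with respect
to every learnable tensor (for training) and with respect to the input node
features (for gradient-based node attribution).  This module provides the
small set of differentiable primitives those computations require, in
float64, with full broadcasting support.  Everything is eager: each op
records a closure that accumulates into ``parent.grad`` when
:meth:`Tensor.backward` is called on a scalar result.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal -------------------------------------------------
    def backward(self):
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

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            _accum(self, _unbroadcast(g, self.shape))
            _accum(other, _unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: _accum(self, -g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            _accum(self, _unbroadcast(g * other.data, self.shape))
            _accum(other, _unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, (self,))
        out._backward = lambda g: _accum(
            self, _unbroadcast(g * p * self.data ** (p - 1), self.shape))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), (self, other))

        def bw(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            _accum(self, _unbroadcast(ga, self.shape))
            _accum(other, _unbroadcast(gb, other.shape))

        out._backward = bw
        return out

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            _accum(self, np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def transpose_last(self):
        out = Tensor(np.swapaxes(self.data, -1, -2), (self,))
        out._backward = lambda g: _accum(self, np.swapaxes(g, -1, -2))
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray):
    if t.grad is None:
        # copy: g may alias another tensor's gradient buffer
        t.grad = np.array(g, dtype=np.float64)
    else:
        t.grad += g


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, (x,))
    out._backward = lambda g: _accum(x, g * s * (1.0 - s))
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-CDF GELU, gelu(x) = x * Phi(x)."""
    phi_cdf = 0.5 * (1.0 + erf(x.data / _SQRT2))
    out = Tensor(x.data * phi_cdf, (x,))

    def bw(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data ** 2)
        _accum(x, g * (phi_cdf + x.data * pdf))

    out._backward = bw
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = Tensor(e, (x,))
    out._backward = lambda g: _accum(x, g * e)
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), (x,))
    out._backward = lambda g: _accum(x, g / x.data)
    return out


# ---------------------------------------------------------------------------
# structured ops
# ---------------------------------------------------------------------------

def masked_softmax(scores: Tensor, mask: np.ndarray | None) -> Tensor:
    """Row softmax over the last axis; positions where ``mask`` is 0 get
    probability exactly 0 (scores treated as -inf).  A row with no allowed
    position would be ill-defined; callers guarantee the diagonal is kept."""
    s = scores.data
    if mask is not None:
        s = np.where(mask.astype(bool), s, -np.inf)
    m = np.max(s, axis=-1, keepdims=True)
    e = np.exp(s - m)
    p = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(p, (scores,))

    def bw(g):
        dot = (g * p).sum(axis=-1, keepdims=True)
        _accum(scores, p * (g - dot))

    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """LayerNorm over the last axis with learnable scale/offset."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data, (x, gamma, beta))
    d = x.data.shape[-1]

    def bw(g):
        _accum(gamma, _unbroadcast(g * xhat, gamma.shape))
        _accum(beta, _unbroadcast(g, beta.shape))
        gx = g * gamma.data
        gxhat_sum = gx.sum(axis=-1, keepdims=True)
        gxhat_dot = (gx * xhat).sum(axis=-1, keepdims=True)
        _accum(x, inv * (gx - gxhat_sum / d - xhat * gxhat_dot / d))

    out._backward = bw
    return out


def max_pool_nodes(x: Tensor, axis: int = -2) -> Tensor:
    """Elementwise max over the node axis; ties route gradient to the
    first maximal index (numpy argmax convention)."""
    out_data = x.data.max(axis=axis)
    idx = np.expand_dims(x.data.argmax(axis=axis), axis)
    out = Tensor(out_data, (x,))

    def bw(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx, np.expand_dims(g, axis), axis=axis)
        _accum(x, gx)

    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    out._backward = bw
    return out


def fused_attention(scores: Tensor, V: Tensor, mask: np.ndarray | None,
                    edge_weights: np.ndarray,
                    drop: np.ndarray | None = None
                    ) -> tuple[Tensor, np.ndarray]:
    """softmax -> (dropout) -> Hadamard with edge weights -> matmul with V,
    as one tape node (the hot path of graph attention).

    Returns the context tensor and the pre-Hadamard attention matrix as a
    plain array.  Gradients flow to ``scores`` and ``V`` only.
    """
    s = scores.data
    if mask is not None:
        s = np.where(mask.astype(bool), s, -np.inf)
    m = np.max(s, axis=-1, keepdims=True)
    e = np.exp(s - m)
    alpha = e / e.sum(axis=-1, keepdims=True)
    hadamard = edge_weights if drop is None else edge_weights * drop
    eff = alpha * hadamard
    out = Tensor(np.matmul(eff, V.data), (scores, V))

    def bw(g):
        _accum(V, np.matmul(np.swapaxes(eff, -1, -2), g))
        d_alpha = np.matmul(g, np.swapaxes(V.data, -1, -2)) * hadamard
        dot = (d_alpha * alpha).sum(axis=-1, keepdims=True)
        _accum(scores, alpha * (d_alpha - dot))

    out._backward = bw
    return out, alpha


def clip_min(x: Tensor, lo: float) -> Tensor:
    """max(x, lo); subgradient 0 where clipped."""
    keep = x.data > lo
    out = Tensor(np.where(keep, x.data, lo), (x,))
    out._backward = lambda g: _accum(x, g * keep)
    return out
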