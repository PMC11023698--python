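"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape: each :class:`Tensor` wraps an ndarray and remembers how to
push its gradient to its parents. The op set is exactly what the
edge-enhanced graph transformer needs — dense linear algebra, gather /
segment-scatter for sparse message passing, a numerically stable fused
segment softmax, layer normalization, and a masked binary cross-entropy
head. Gradients are exact (verified against finite differences in the
test suite).
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self, seed=None):
        """Accumulate gradients of a scalar (or seeded) output into .grad."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data) if seed is None else np.asarray(seed, float)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        self.grad = g if self.grad is None else self.grad + g

    # operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    out._backward = backward
    return out


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data / b.data, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / b.data ** 2, b.shape))

    out._backward = backward
    return out


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, (a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    out._backward = backward
    return out


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.reshape(shape), (a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    out._backward = backward
    return out


def concat(tensors, axis=-1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, gi in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(gi)

    out._backward = backward
    return out


def gather(a, idx) -> Tensor:
    """Row gather: out[k] = a[idx[k]]."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(a.data[idx], (a,))

    def backward(g):
        if a.requires_grad:
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            a._accumulate(acc)

    out._backward = backward
    return out


def segment_sum(a, seg, n_seg) -> Tensor:
    """out[k] = sum of rows of a whose segment id is k."""
    a = as_tensor(a)
    seg = np.asarray(seg, dtype=np.int64)
    data = np.zeros((n_seg,) + a.data.shape[1:])
    np.add.at(data, seg, a.data)
    out = Tensor(data, (a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[seg])

    out._backward = backward
    return out


def segment_mean(a, seg, n_seg) -> Tensor:
    counts = np.bincount(np.asarray(seg), minlength=n_seg).astype(float)
    counts = np.maximum(counts, 1.0)
    total = segment_sum(a, seg, n_seg)
    shape = (n_seg,) + (1,) * (total.data.ndim - 1)
    return mul(total, 1.0 / counts.reshape(shape))


def segment_softmax(logits, seg, n_seg) -> Tensor:
    """Softmax over rows sharing a segment id, per trailing column.

    Numerically stabilized by subtracting the per-segment maximum (a
    constant w.r.t. the gradient).
    """
    logits = as_tensor(logits)
    seg = np.asarray(seg, dtype=np.int64)
    m = np.full((n_seg,) + logits.data.shape[1:], -np.inf)
    np.maximum.at(m, seg, logits.data)
    z = np.exp(logits.data - m[seg])
    s = np.zeros_like(m)
    np.add.at(s, seg, z)
    alpha = z / s[seg]
    out = Tensor(alpha, (logits,))

    def backward(g):
        if logits.requires_grad:
            dot = np.zeros_like(s)
            np.add.at(dot, seg, alpha * g)
            logits._accumulate(alpha * (g - dot[seg]))

    out._backward = backward
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
    out = Tensor(s, (a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    out._backward = backward
    return out


def elu(a) -> Tensor:
    """Exponential linear unit — the package's single smooth nonlinearity."""
    a = as_tensor(a)
    neg = np.exp(np.minimum(a.data, 0.0)) - 1.0
    out = Tensor(np.where(a.data > 0, a.data, neg), (a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * np.where(a.data > 0, 1.0, neg + 1.0))

    out._backward = backward
    return out


def mean_all(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.mean(), (a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.full_like(a.data, g / a.data.size))

    out._backward = backward
    return out


def layer_norm(x, gain, bias, eps: float = 1e-5) -> Tensor:
    """Row-wise layer normalization with learnable gain and bias."""
    x, gain, bias = as_tensor(x), as_tensor(gain), as_tensor(bias)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gain.data + bias.data, (x, gain, bias))

    def backward(g):
        if gain.requires_grad:
            gain._accumulate(_unbroadcast(g * xhat, gain.shape))
        if bias.requires_grad:
            bias._accumulate(_unbroadcast(g, bias.shape))
        if x.requires_grad:
            dxhat = g * gain.data
            d = dxhat.shape[-1]
            dx = (dxhat - dxhat.mean(axis=-1, keepdims=True)
                  - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)) * inv
            x._accumulate(dx)

    out._backward = backward
    return out


def dropout(x, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0:
        return as_tensor(x)
    keep = (rng.random(as_tensor(x).shape) >= p).astype(float) / (1.0 - p)
    return mul(x, keep)


def masked_bce_with_logits(logits, labels, mask) -> Tensor:
    """Mean binary cross-entropy over the cells where mask is nonzero.

    Masked cells contribute exactly zero to the value and the gradient.
    """
    logits = as_tensor(logits)
    y = np.asarray(labels, float)
    m = np.asarray(mask, float)
    count = m.sum()
    if count == 0:
        raise ValueError("all prediction cells are masked; no loss to compute")
    z = logits.data
    per_cell = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor((per_cell * m).sum() / count, (logits,))

    def backward(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate(g * (s - y) * m / count)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Linear:
    """Affine map with Glorot-uniform initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = parameter(rng.uniform(-limit, limit, size=(d_in, d_out)))
        self.b = parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x) -> Tensor:
        out = matmul(x, self.W)
        return add(out, self.b) if self.b is not None else out

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class MLP:
    """Stack of Linear layers with ELU between them (none after the last)."""

    def __init__(self, widths, rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]

    def __call__(self, x, dropout_p: float = 0.0,
                 rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        for k, layer in enumerate(self.layers):
            x = layer(x)
            if k < len(self.layers) - 1:
                x = elu(x)
                x = dropout(x, dropout_p, rng, training)
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class LayerNorm:
    def __init__(self, d: int):
        self.gain = parameter(np.ones(d))
        self.bias = parameter(np.zeros(d))

    def __call__(self, x) -> Tensor:
        return layer_norm(x, self.gain, self.bias)

    def parameters(self):
        return [self.gain, self.bias]


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        for k, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
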