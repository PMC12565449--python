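"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides exactly the primitives the learned paths of the package
need (dense/convolutional layers, windowed multi-head self-attention,
layer normalisation, max pooling, softmax cross-entropy) together with
Adam/AdamW optimisers.  It is deliberately small: tensors are float64 by
default, everything runs on a single CPU, and the computation graph is a
plain tape freed after each backward pass.

All randomness (initialisation, dropout, batch shuffling) flows through
numpy Generators supplied by the caller, so training is bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Tensor",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "Adam",
    "AdamW",
    "concat",
    "cross_entropy_logits",
    "mse_loss",
]


#: compute dtype of the tape; single precision is plenty for training and
#: halves the arithmetic cost on CPU
DTYPE = np.float32


class Tensor:
    """Array node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion
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
                node._backward()
            # free the closure so intermediate buffers can be collected
            node._backward = None
            node._parents = ()

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_grad(*ts: Tensor) -> bool:
    return any(t.requires_grad for t in ts)


def _make(data, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _needs_grad(*parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward():
        g = out.grad
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward():
        g = out.grad
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward():
        g = out.grad
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def reshape(x, shape) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.reshape(shape)

    def backward():
        if x.requires_grad:
            x._accum(out.grad.reshape(x.shape))

    out = _make(out_data, (x,), backward)
    return out


def transpose(x, axes) -> Tensor:
    x = _as_tensor(x)
    axes = tuple(axes)
    out_data = np.transpose(x.data, axes)
    inv = tuple(np.argsort(axes))

    def backward():
        if x.requires_grad:
            x._accum(np.transpose(out.grad, inv))

    out = _make(out_data, (x,), backward)
    return out


def roll2d(x, shifts: tuple[int, int], axes: tuple[int, int]) -> Tensor:
    """Cyclic shift (used by shifted-window attention)."""
    x = _as_tensor(x)
    out_data = np.roll(x.data, shifts, axis=axes)

    def backward():
        if x.requires_grad:
            x._accum(np.roll(out.grad, (-shifts[0], -shifts[1]), axis=axes))

    out = _make(out_data, (x,), backward)
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        g = out.grad
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out = _make(out_data, tuple(tensors), backward)
    return out


def relu(x) -> Tensor:
    x = _as_tensor(x)
    out_data = np.maximum(x.data, 0.0)

    def backward():
        if x.requires_grad:
            x._accum(out.grad * (x.data > 0))

    out = _make(out_data, (x,), backward)
    return out


def gelu(x) -> Tensor:
    """Exact GELU, x * Phi(x), with the erf form."""
    x = _as_tensor(x)
    phi = 0.5 * (1.0 + erf(x.data / math.sqrt(2.0)))
    out_data = x.data * phi

    def backward():
        if x.requires_grad:
            pdf = np.exp(-0.5 * x.data**2) / math.sqrt(2.0 * math.pi)
            x._accum(out.grad * (phi + x.data * pdf))

    out = _make(out_data, (x,), backward)
    return out


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward():
        if x.requires_grad:
            x._accum(out.grad * out_data * (1.0 - out_data))

    out = _make(out_data, (x,), backward)
    return out


def softmax(x, axis: int = -1) -> Tensor:
    x = _as_tensor(x)
    z = x.data - np.max(x.data, axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward():
        if x.requires_grad:
            g = out.grad
            dot = np.sum(g * out_data, axis=axis, keepdims=True)
            x._accum(out_data * (g - dot))

    out = _make(out_data, (x,), backward)
    return out


def tsum(x, axis=None, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward():
        if x.requires_grad:
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            x._accum(np.broadcast_to(g, x.shape).copy())

    out = _make(out_data, (x,), backward)
    return out


def tmean(x, axis=None, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / float(n))


def tmax(x, axis: int, keepdims: bool = False) -> Tensor:
    """Max reduction; ties route the gradient to the first maximiser."""
    x = _as_tensor(x)
    out_data = x.data.max(axis=axis, keepdims=keepdims)
    idx = np.argmax(x.data, axis=axis)

    def backward():
        if x.requires_grad:
            g = out.grad
            if not keepdims:
                g = np.expand_dims(g, axis)
            mask = np.zeros_like(x.data)
            np.put_along_axis(mask, np.expand_dims(idx, axis), 1.0, axis=axis)
            x._accum(mask * g)

    out = _make(out_data, (x,), backward)
    return out


def dropout(x, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (inference) or p == 0."""
    x = _as_tensor(x)
    if rng is None or p <= 0.0:
        return x
    keep = ((rng.random(x.shape) >= p) / (1.0 - p)).astype(DTYPE)

    def backward():
        if x.requires_grad:
            x._accum(out.grad * keep)

    out = _make(x.data * keep, (x,), backward)
    return out


def layer_norm(x, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    x = _as_tensor(x)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def backward():
        g = out.grad
        n = x.shape[-1]
        if gamma.requires_grad:
            gamma._accum((g * xhat).reshape(-1, n).sum(axis=0))
        if beta.requires_grad:
            beta._accum(g.reshape(-1, n).sum(axis=0))
        if x.requires_grad:
            gx = g * gamma.data
            dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                        - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
            x._accum(dx)

    out = _make(out_data, (x, gamma, beta), backward)
    return out


def maxpool2d(x) -> Tensor:
    """2x2 max pooling with stride 2 on (N, C, H, W)."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2d requires even spatial dims")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    x4 = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = np.argmax(x4, axis=-1)
    out_data = np.take_along_axis(x4, idx[..., None], axis=-1)[..., 0]

    def backward():
        if x.requires_grad:
            g4 = np.zeros((n, c, h // 2, w // 2, 4))
            np.put_along_axis(g4, idx[..., None], out.grad[..., None], axis=-1)
            gx = g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accum(gx.reshape(n, c, h, w))

    out = _make(out_data, (x,), backward)
    return out


def upsample2(x) -> Tensor:
    """Nearest-neighbour 2x upsampling on (N, C, H, W)."""
    x = _as_tensor(x)
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward():
        if x.requires_grad:
            n, c, h, w = x.shape
            g = out.grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
            x._accum(g)

    out = _make(out_data, (x,), backward)
    return out


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patches for stride-1 convolution."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    n, c, h, w = cols.shape[:4]
    return cols.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


def conv2d(x, weight: Tensor, bias: Tensor | None, pad: int) -> Tensor:
    """Stride-1 2-D cross-correlation, NCHW layout, square odd kernel."""
    x = _as_tensor(x)
    o, c, k, _ = weight.shape
    n, _, h, w = x.shape
    ho, wo = h + 2 * pad - k + 1, w + 2 * pad - k + 1
    cols = _im2col(x.data, k, pad)[:, : (h + 2 * pad - k + 1) * (w + 2 * pad - k + 1)]
    wmat = weight.data.reshape(o, c * k * k)
    out_data = (cols @ wmat.T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    def backward():
        g = out.grad  # (N, O, Ho, Wo)
        gmat = g.transpose(0, 2, 3, 1).reshape(n, ho * wo, o)
        if weight.requires_grad:
            cols_b = _im2col(x.data, k, pad)
            gw = gmat.reshape(-1, o).T @ cols_b.reshape(-1, c * k * k)
            weight._accum(gw.reshape(o, c, k, k))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # full correlation of the output grad with the flipped kernel
            wflip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,O,k,k)
            pad_b = k - 1 - pad
            cols_g = _im2col(g, k, pad_b)
            wmat_b = wflip.reshape(c, o * k * k)
            gx = (cols_g @ wmat_b.T).reshape(n, h, w, c).transpose(0, 3, 1, 2)
            x._accum(gx)

    out = _make(out_data, (x, weight) + (() if bias is None else (bias,)), backward)
    return out


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels against raw logits (N, K)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    n = logits.shape[0]
    loss = -logp[np.arange(n), labels].mean()

    def backward():
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits._accum(out.grad * p / n)

    out = _make(loss, (logits,), backward)
    return out


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = add(pred, Tensor(-np.asarray(target, dtype=DTYPE)))
    return tmean(mul(diff, diff))


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter bookkeeping only."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: Iterable[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data[...] = s


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = math.sqrt(2.0 / (d_in + d_out))
        self.weight = Tensor(rng.normal(0.0, scale, (d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        return y if self.bias is None else add(y, self.bias)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 pad: int | None = None):
        scale = math.sqrt(2.0 / (c_in * k * k))
        self.weight = Tensor(rng.normal(0.0, scale, (c_out, c_in, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.pad = k // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.pad)


class LayerNorm(Module):
    def __init__(self, d: int):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MultiHeadSelfAttention(Module):
    """Multi-head self-attention over (..., T, D) with an optional additive
    mask broadcastable to the attention logits (..., heads, T, T)."""

    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        if d % heads:
            raise ValueError("model width must divide the head count")
        self.d, self.heads = d, heads
        self.qkv = Linear(d, 3 * d, rng)
        self.proj = Linear(d, d, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None,
                 return_attn: bool = False):
        *lead, t, d = x.shape
        h, dh = self.heads, self.d // self.heads
        qkv = self.qkv(x)  # (..., T, 3D)
        qkv = reshape(qkv, tuple(lead) + (t, 3, h, dh))
        nl = len(lead)
        # (..., 3, h, T, dh)
        qkv = transpose(qkv, tuple(range(nl)) + (nl + 1, nl + 2, nl, nl + 3))
        idx_q = (slice(None),) * nl + (0,)
        q = _index(qkv, idx_q)
        k = _index(qkv, (slice(None),) * nl + (1,))
        v = _index(qkv, (slice(None),) * nl + (2,))
        kt = transpose(k, tuple(range(nl + 1)) + (nl + 2, nl + 1))
        logits = mul(matmul(q, kt), 1.0 / math.sqrt(dh))
        if mask is not None:
            logits = add(logits, Tensor(mask))
        attn = softmax(logits, axis=-1)
        ctx = matmul(attn, v)  # (..., h, T, dh)
        ctx = transpose(ctx, tuple(range(nl)) + (nl + 1, nl, nl + 2))
        ctx = reshape(ctx, tuple(lead) + (t, d))
        out = self.proj(ctx)
        if return_attn:
            return out, attn
        return out


def _index(x: Tensor, idx) -> Tensor:
    out_data = x.data[idx]

    def backward():
        if x.requires_grad:
            g = np.zeros_like(x.data)
            g[idx] = out.grad
            x._accum(g)

    out = _make(np.ascontiguousarray(out_data), (x,), backward)
    return out


class TransformerBlock(Module):
    """Pre-norm transformer encoder block (MHSA + GELU MLP)."""

    def __init__(self, d: int, heads: int, d_ff: int, rng: np.random.Generator,
                 drop: float = 0.0):
        self.norm1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, heads, rng)
        self.norm2 = LayerNorm(d)
        self.fc1 = Linear(d, d_ff, rng)
        self.fc2 = Linear(d_ff, d, rng)
        self.drop = drop

    def __call__(self, x: Tensor, mask: np.ndarray | None = None,
                 rng: np.random.Generator | None = None) -> Tensor:
        a = self.attn(self.norm1(x), mask=mask)
        x = add(x, dropout(a, self.drop, rng))
        m = self.fc2(dropout(gelu(self.fc1(self.norm2(x))), self.drop, rng))
        return add(x, dropout(m, self.drop, rng))


# ---------------------------------------------------------------------------
# optimisers
# ---------------------------------------------------------------------------

def clip_grad_norm(params: Sequence[Tensor], max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = math.sqrt(total)
    if np.isfinite(norm) and norm > max_norm > 0:
        scale = DTYPE(max_norm / norm)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """Adam; weight decay (if any) is L2-coupled as in the original method.

    ``decay_mask`` restricts weight decay to selected parameters; by
    convention biases and normalisation parameters are excluded (pass
    ``[p.data.ndim > 1 for p in params]``).
    """

    decoupled = False

    def __init__(self, params: Sequence[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0,
                 decay_mask: Sequence[bool] | None = None):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.decay_mask = (list(decay_mask) if decay_mask is not None
                           else [True] * len(self.params))
        # moments kept in double precision: squared gradients can overflow
        # single precision range during transients
        self.m = [np.zeros(p.data.shape, dtype=np.float64) for p in self.params]
        self.v = [np.zeros(p.data.shape, dtype=np.float64) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = (p.grad if p.grad is not None
                 else np.zeros_like(p.data)).astype(np.float64)
            wd = self.weight_decay if self.decay_mask[i] else 0.0
            if wd and not self.decoupled:
                g = g + wd * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            if wd and self.decoupled:
                p.data -= DTYPE(self.lr * wd) * p.data
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)
                       ).astype(p.data.dtype)


class AdamW(Adam):
    """Adam with decoupled weight decay."""

    decoupled = True
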