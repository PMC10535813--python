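"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the pigment-decomposition network needs:
2-D convolution (im2col), leaky ReLU, sigmoid, addition, channel
concatenation, nearest-neighbour upsampling, and a masked mean-squared-error
reduction.  Arrays are NCHW float32.  Each operation builds a closure that
accumulates gradients into its parents; ``Tensor.backward`` runs them in
reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "leaky_relu",
    "sigmoid",
    "add",
    "concat",
    "upsample2",
    "masked_mse_loss",
]


#: Working dtype of the engine; float32 for speed.  Tests may switch to
#: float64 for tight finite-difference gradient verification.
DTYPE = np.float32


class Tensor:
    """A numpy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self._parents
        )

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion limits
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = np.ascontiguousarray(view).reshape(n, c * kh * kw, oh * ow)
    return cols, oh, ow


def _col2im(dcols, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    d6 = dcols.reshape(n, c, kh, kw, oh, ow)
    gx = np.zeros((n, c, hp, wp), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d6[
                :, :, i, j
            ]
    if pad:
        gx = gx[:, :, pad : pad + h, pad : pad + w]
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1,
           pad: int | None = None) -> Tensor:
    """NCHW convolution; default 'same' padding for stride 1."""
    oc, ic, kh, kw = w.shape
    if pad is None:
        pad = kh // 2
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    w2 = w.data.reshape(oc, ic * kh * kw)
    out = np.matmul(w2, cols)  # (n, oc, oh*ow)
    out += b.data[None, :, None]
    n = x.data.shape[0]
    out = out.reshape(n, oc, oh, ow)

    def backward(g):
        g2 = np.ascontiguousarray(g).reshape(n, oc, oh * ow)
        if w.requires_grad:
            dw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(dw.reshape(w.shape))
        if b.requires_grad:
            b._accumulate(g2.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2)
            x._accumulate(_col2im(dcols, x.data.shape, kh, kw, stride, pad))

    return Tensor(out, (x, w, b), backward)


def leaky_relu(x: Tensor, alpha: float = 0.1) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, alpha * x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.where(mask, g, alpha * g))

    return Tensor(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    z = np.clip(x.data, -60.0, 60.0)  # avoids float32 exp overflow; grad ~0 there
    out = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out * (1.0 - out))

    return Tensor(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return Tensor(out, (a, b), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out, tuple(tensors), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h, w = g.shape
            x._accumulate(
                g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
            )

    return Tensor(out, (x,), backward)


def bounded_linear(x: Tensor, alpha: float = 0.05) -> Tensor:
    """Clip to [0, 1] with leaky gradients outside the bounds.

    Used as the map head: outputs are hard-bounded, yet saturated pixels
    retain an ``alpha`` fraction of their gradient and can re-enter the
    interior — unlike a sigmoid, whose gradient vanishes at the rails.
    """
    out = np.clip(x.data, 0.0, 1.0)
    inside = (x.data > 0.0) & (x.data < 1.0)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.where(inside, g, alpha * g))

    return Tensor(out, (x,), backward)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    """Group normalization over (channels/groups, H, W) per sample."""
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError("channels must divide evenly into groups")
    xg = x.data.reshape(n, groups, c // groups, h, w)
    mu = xg.mean(axis=(2, 3, 4), keepdims=True)
    var = xg.var(axis=(2, 3, 4), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(n, c, h, w)
    out = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gy = (g * gamma.data[None, :, None, None]).reshape(
                n, groups, c // groups, h, w
            )
            xh = xhat.reshape(n, groups, c // groups, h, w)
            m1 = gy.mean(axis=(2, 3, 4), keepdims=True)
            m2 = (gy * xh).mean(axis=(2, 3, 4), keepdims=True)
            dx = (gy - m1 - xh * m2) * inv
            x._accumulate(dx.reshape(n, c, h, w))

    return Tensor(out, (x, gamma, beta), backward)


def masked_log_mse_loss(pred: Tensor, target: np.ndarray, mask: np.ndarray,
                        eps: float = 1e-2) -> Tensor:
    """Mean squared error between log-intensities over masked pixels.

    Operating on ``log(I + eps)`` equalizes the fractional error across
    channels, so dim channels (green/blue under skin absorption) carry the
    same weight as the bright red channel — the log domain is also the one
    in which pigment amounts act linearly (optical density).
    """
    m = np.asarray(mask, bool)[:, None, :, :]
    count = m.sum() * pred.data.shape[1]
    if count == 0:
        raise ValueError("mask selects no pixels")
    pd = np.maximum(pred.data, 0.0)
    diff = np.where(
        m,
        np.log(pd + eps) - np.log(np.maximum(np.asarray(target, DTYPE), 0) + eps),
        0.0,
    )
    out = np.array((diff * diff).sum() / count, dtype=DTYPE)

    def backward(g):
        if pred.requires_grad:
            grad = g * 2.0 * diff / count / (pd + eps)
            # negative predictions were floored at 0: only gradients pushing
            # them further down are silenced
            grad = np.where(pred.data > 0, grad, np.minimum(grad, 0.0))
            pred._accumulate(grad.astype(DTYPE))

    return Tensor(out, (pred,), backward)


def masked_mse_loss(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean squared error over pixels where ``mask`` is true.

    ``mask`` has shape (N, H, W) and is broadcast over channels.
    """
    m = np.asarray(mask, bool)[:, None, :, :]
    count = m.sum() * pred.data.shape[1]
    if count == 0:
        raise ValueError("mask selects no pixels")
    diff = np.where(m, pred.data - np.asarray(target, DTYPE), 0.0)
    out = np.array((diff * diff).sum() / count, dtype=DTYPE)

    def backward(g):
        if pred.requires_grad:
            pred._accumulate(g * 2.0 * diff / count)

    return Tensor(out, (pred,), backward)
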