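"""Residual encoder-decoder emitting melanin, hemoglobin and shading maps.

A compact U-shaped network in the ResUNet family: a convolutional stem,
``depth`` residual downsampling stages, a residual bottleneck, and mirrored
upsampling stages with skip concatenation, ending in a 1x1 head whose
leaky-clipped linear activation bounds all three output maps to [0, 1]
while keeping gradients alive at the bounds.  Channel width doubles per
stage from ``base_channels``, capped at ``max_width_factor`` times the base
(default 2x) to keep the desk-scale model CPU-trainable.
"""

from __future__ import annotations

import numpy as np

from . import autograd
from .autograd import (Tensor, add, bounded_linear, concat, conv2d,
                       leaky_relu, sigmoid, upsample2)

__all__ = ["ResUNet"]


def _he_init(rng, oc, ic, kh, kw):
    fan_in = ic * kh * kw
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(oc, ic, kh, kw)).astype(
        autograd.DTYPE
    )


class _Conv:
    def __init__(self, rng, ic, oc, k=3, stride=1):
        self.w = Tensor(_he_init(rng, oc, ic, k, k), requires_grad=True)
        self.b = Tensor(np.zeros(oc, autograd.DTYPE), requires_grad=True)
        self.stride = stride
        self.pad = k // 2

    def __call__(self, x):
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    @property
    def params(self):
        return [self.w, self.b]


class _Scale:
    """Learnable scalar gate on the residual branch, initialized small.

    A norm-free stabilization: keeps the residual trunk close to identity at
    initialization so activations cannot compound through depth.
    """

    def __init__(self, init=0.3):
        self.s = Tensor(np.array([init], autograd.DTYPE), requires_grad=True)

    def __call__(self, x):
        s = self.s

        def backward(g):
            if s.requires_grad:
                s._accumulate(np.array([(g * x.data).sum()], dtype=g.dtype))
            if x.requires_grad:
                x._accumulate(g * s.data[0])

        return Tensor(x.data * s.data[0], (x, s), backward)

    @property
    def params(self):
        return [self.s]


class _ResBlock:
    """Pre-activation residual block with a scaled branch:
    x + s * conv(lrelu(conv(lrelu(x))))."""

    def __init__(self, rng, channels):
        self.c1 = _Conv(rng, channels, channels)
        self.c2 = _Conv(rng, channels, channels)
        self.gate = _Scale()

    def __call__(self, x):
        h = self.c1(leaky_relu(x))
        h = self.c2(leaky_relu(h))
        return add(x, self.gate(h))

    @property
    def params(self):
        return self.c1.params + self.c2.params + self.gate.params


class ResUNet:
    """Encoder-decoder with residual blocks and skip connections.

    Input: (N, 3, H, W) linear-RGB patches with H, W divisible by
    ``2**depth``.  Output: (N, 3, H, W) maps bounded to [0, 1], ordered
    (melanin, hemoglobin, shading).
    """

    def __init__(self, base_channels: int = 16, depth: int = 4, seed: int = 0,
                 max_width_factor: int = 2):
        if base_channels < 1 or depth < 1:
            raise ValueError("base_channels and depth must be positive")
        self.base_channels = base_channels
        self.depth = depth
        self.seed = seed
        self.max_width_factor = max_width_factor
        rng = np.random.default_rng(seed)
        chans = [
            min(base_channels * 2**i, base_channels * max_width_factor)
            for i in range(depth + 1)
        ]
        self.chans = chans
        self.stem = _Conv(rng, 3, chans[0])
        self.enc_blocks = [_ResBlock(rng, chans[i]) for i in range(depth)]
        self.downs = [_Conv(rng, chans[i], chans[i + 1], stride=2) for i in range(depth)]
        self.bottleneck = _ResBlock(rng, chans[depth])
        self.up_convs = [
            _Conv(rng, chans[i + 1], chans[i]) for i in reversed(range(depth))
        ]
        self.merge_convs = [
            _Conv(rng, 2 * chans[i], chans[i]) for i in reversed(range(depth))
        ]
        self.dec_blocks = [_ResBlock(rng, chans[i]) for i in reversed(range(depth))]
        self.head = _Conv(rng, chans[0], 3, k=1)
        # start the maps at physiological prior means with small spread, so
        # the hard-bounded head begins inside its active region and the
        # first rendered guesses resemble lightly pigmented skin; a neutral
        # 0.5 start renders far too dark and drives melanin into the lower
        # bound, a constrained local minimum of the reconstruction loss
        self.head.w.data *= 0.1
        self.head.b.data[:] = np.array([0.15, 0.5, 0.85], autograd.DTYPE)

    @property
    def params(self) -> list[Tensor]:
        out = list(self.stem.params)
        for m in self.enc_blocks + self.downs:
            out += m.params
        out += self.bottleneck.params
        for m in self.up_convs + self.merge_convs + self.dec_blocks:
            out += m.params
        out += self.head.params
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params)

    def __call__(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        h, w = x.shape[2], x.shape[3]
        f = 2**self.depth
        if h % f or w % f:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 2**depth = {f}"
            )
        t = self.stem(x)
        skips = []
        for block, down in zip(self.enc_blocks, self.downs):
            t = block(t)
            skips.append(t)
            t = down(t)
        t = self.bottleneck(t)
        for up, merge, block, skip in zip(
            self.up_convs, self.merge_convs, self.dec_blocks, reversed(skips)
        ):
            t = up(upsample2(t))
            t = merge(concat([t, skip]))
            t = block(t)
        return bounded_linear(self.head(leaky_relu(t)))

    # --- parameter (de)serialization ------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params
        if len(state) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], autograd.DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter p{i} shape mismatch")
            p.data = arr.copy()
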