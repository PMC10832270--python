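"""Convolutional Block Attention Module (CBAM): channel then spatial gating.

Channel attention squeezes each channel to its global average and global max,
pushes both descriptors through one shared two-layer bottleneck (C -> C/r -> C,
ReLU between), mixes the two paths with trainable scalars alpha and beta, and
gates channels with a sigmoid:

    M_c = sigma(alpha * FC(GAP(x)) + beta * FC(GMP(x))),   y_c = M_c * x_c

Spatial attention then pools the channel-attended map across channels (mean
and max per position), merges the two maps — summation by default, with the
two-channel concatenation variant selectable — runs a 7x7 convolution and a
sigmoid, and gates positions:

    S = sigma(conv7(avg_c(y) + max_c(y))),   out = S ⊙ y

The two stages are applied strictly in series: spatial attention always sees
the channel-attended map, never the raw input.
"""

from __future__ import annotations

import numpy as np

from . import nd
from .nd import Tensor

__all__ = ["channel_pool", "spatial_pool", "ChannelAttention", "SpatialAttention", "CBAM"]


def _batched(x):
    x = nd.as_tensor(x)
    if x.ndim == 3:
        return x.reshape(1, *x.shape), True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"expected CxHxW or NxCxHxW feature map, got shape {x.shape}")


def channel_pool(x):
    """Global average and global max per channel: (gap, gmp), each (N,)C."""
    xb, squeeze = _batched(x)
    gap = xb.mean(axis=(2, 3))
    gmp = xb.max(axis=(2, 3))
    if squeeze:
        gap, gmp = gap.reshape(gap.shape[1]), gmp.reshape(gmp.shape[1])
    return gap, gmp


def spatial_pool(x):
    """Per-position mean and max across channels: (favg, fmax), each (N,)HxW."""
    xb, squeeze = _batched(x)
    favg = xb.mean(axis=1)
    fmax = xb.max(axis=1)
    if squeeze:
        favg, fmax = favg.reshape(favg.shape[1:]), fmax.reshape(fmax.shape[1:])
    return favg, fmax


class ChannelAttention(nd.Module):
    """Shared-bottleneck channel gate with trainable path weights alpha, beta."""

    def __init__(self, channels: int, reduction: int = 16, rng=None):
        super().__init__()
        self.channels = channels
        hidden = max(1, channels // reduction)
        self.fc1 = nd.Linear(channels, hidden, bias=False, rng=rng)
        self.fc2 = nd.Linear(hidden, channels, bias=False, rng=rng)
        self.alpha = nd.Parameter(np.array(1.0))
        self.beta = nd.Parameter(np.array(1.0))

    def _fc(self, v: Tensor) -> Tensor:
        # leaky rectifier: a width-1 bottleneck with a hard ReLU goes dead
        # too easily, silencing one pooling path entirely
        return self.fc2(self.fc1(v).leaky_relu(0.1))

    def forward(self, x) -> Tensor:
        """Channel weights M_c in (0,1)^C (batched: N x C)."""
        xb, squeeze = _batched(x)
        if xb.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {xb.shape[1]}")
        gap, gmp = channel_pool(xb)
        mc = (self.alpha * self._fc(gap) + self.beta * self._fc(gmp)).sigmoid()
        return mc.reshape(mc.shape[1]) if squeeze else mc


def apply_channel(x, mc) -> Tensor:
    """Scale each channel of x by its attention weight."""
    xb, squeeze = _batched(x)
    mc = nd.as_tensor(mc)
    if mc.ndim == 1:
        mc = mc.reshape(1, -1)
    y = xb * mc.reshape(*mc.shape, 1, 1)
    return y.reshape(y.shape[1:]) if squeeze else y


class SpatialAttention(nd.Module):
    """7x7-conv spatial gate over channel-pooled maps (sum or concat merge)."""

    def __init__(self, merge: str = "sum", kernel: int = 7, bias: bool = False,
                 sigmoid: bool = True, rng=None):
        super().__init__()
        if merge not in ("sum", "concat"):
            raise ValueError("merge must be 'sum' or 'concat'")
        self.merge = merge
        self.sigmoid = sigmoid
        in_ch = 1 if merge == "sum" else 2
        self.conv = nd.Conv2d(in_ch, 1, kernel, stride=1, padding=kernel // 2,
                              bias=bias, rng=rng)

    def forward(self, x) -> Tensor:
        """Spatial weights S in (0,1)^(HxW) (batched: N x H x W)."""
        xb, squeeze = _batched(x)
        favg, fmax = spatial_pool(xb)
        if self.merge == "sum":
            m = (favg + fmax).reshape(xb.shape[0], 1, *xb.shape[2:])
        else:
            m = nd.stack([favg, fmax], axis=1)
        s = self.conv(m)
        if self.sigmoid:
            s = s.sigmoid()
        s = s.reshape(xb.shape[0], *xb.shape[2:])
        return s.reshape(s.shape[1:]) if squeeze else s


class CBAM(nd.Module):
    """Channel attention followed by spatial attention, in series."""

    def __init__(self, channels: int, reduction: int = 16, merge: str = "sum",
                 sigmoid_spatial: bool = True, rng=None):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(merge=merge, sigmoid=sigmoid_spatial, rng=rng)

    def forward(self, x) -> Tensor:
        xb, squeeze = _batched(x)
        mc = self.channel(xb)
        y = apply_channel(xb, mc)
        s = self.spatial(y)                       # computed on the attended map
        out = y * s.reshape(s.shape[0], 1, *s.shape[1:])
        return out.reshape(out.shape[1:]) if squeeze else out

    def attention_maps(self, x):
        """Return (Mc, S, y) without gradient tracking, for inspection."""
        with nd.no_grad():
            xb, squeeze = _batched(x)
            mc = self.channel(xb)
            y = apply_channel(xb, mc)
            s = self.spatial(y)
            out = y * s.reshape(s.shape[0], 1, *s.shape[1:])
        if squeeze:
            return mc.numpy()[0], s.numpy()[0], out.numpy()[0]
        return mc.numpy(), s.numpy(), out.numpy()
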