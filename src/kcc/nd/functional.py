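"""Convolutional primitives for the autodiff engine.

Convolution is implemented by the im2col/col2im construction: windows of the
(padded) input are gathered into a matrix, the kernel acts as a single GEMM,
and the backward pass scatters window gradients back.  All ops take NCHW
tensors.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor

__all__ = ["conv2d", "max_pool2d", "upsample_nearest", "bce_with_logits", "batch_norm_train"]


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused training-mode batch normalization over (N, H, W) per channel.

    Returns (normalized-and-affine output, batch mean, batch var) — the
    moments as plain arrays for the running-statistics update.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    gb = gamma.data.reshape(1, -1, 1, 1)
    out_data = xhat * gb + beta.data.reshape(1, -1, 1, 1)
    rg = x.requires_grad or gamma.requires_grad or beta.requires_grad

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gb
            m1 = dxhat.mean(axis=axes, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
            x._accum(inv_std * (dxhat - m1 - xhat * m2))

    out = Tensor._make(out_data, (x, gamma, beta), backward, rg)
    return out, mu.ravel(), var.ravel()


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N, C, OH, OW, kh, kw) -> (N, OH*OW, C*kh*kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, oh * ow, c * kh * kw)
    return cols, oh, ow


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dwin = dcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += dwin[..., i, j]
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation; weight shape (Cout, Cin, kh, kw)."""
    x, weight = as_tensor(x), as_tensor(weight)
    n = x.shape[0]
    cout, cin, kh, kw = weight.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, kernel expects {cin}")
    cols, oh, ow = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(cout, -1)
    out_data = cols @ wmat.T                      # (N, OH*OW, Cout)
    if bias is not None:
        out_data = out_data + bias.data
    out_data = out_data.transpose(0, 2, 1).reshape(n, cout, oh, ow)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    rg = any(p.requires_grad for p in parents)

    def backward(g):
        gmat = g.reshape(n, cout, oh * ow).transpose(0, 2, 1)   # (N, OH*OW, Cout)
        if weight.requires_grad:
            dw = np.tensordot(gmat, cols, axes=([0, 1], [0, 1]))
            weight._accum(dw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=(0, 1)))
        if x.requires_grad:
            dcols = gmat @ wmat                                  # (N, OH*OW, C*kh*kw)
            x._accum(_col2im(dcols, x.shape, kh, kw, stride, padding))

    return Tensor._make(out_data, parents, backward, rg)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    stride = stride or kernel
    n, c, h, w = x.shape
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    oh = (h + 2 * padding - kernel) // stride + 1
    ow = (w + 2 * padding - kernel) // stride + 1
    win = sliding_window_view(xd, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = win.reshape(n, c, oh, ow, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        dxp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=g.dtype)
        ii, jj = np.divmod(arg, kernel)
        oy, ox = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
        rows = (oy * stride + ii).reshape(n, c, -1)
        colsix = (ox * stride + jj).reshape(n, c, -1)
        nn = np.arange(n)[:, None, None]
        cc = np.arange(c)[None, :, None]
        np.add.at(dxp, (nn, cc, rows, colsix), g.reshape(n, c, -1))
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)

    return Tensor._make(out_data, (x,), backward, x.requires_grad)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.shape
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    def backward(g):
        x._accum(g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), backward, x.requires_grad)


def bce_with_logits(logits: Tensor, targets, weights=None, reduction: str = "mean") -> Tensor:
    """Numerically stable binary cross-entropy on raw logits.

    loss = max(z,0) - z*t + log(1 + exp(-|z|)); optional per-element weights.
    """
    logits = as_tensor(logits)
    t = np.asarray(targets, dtype=logits.data.dtype)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    warr = None if weights is None else np.asarray(weights, dtype=z.dtype)
    if warr is not None:
        loss = loss * warr
    if reduction == "mean":
        out_data, scale = loss.mean(), 1.0 / loss.size
    elif reduction == "sum":
        out_data, scale = loss.sum(), 1.0
    else:
        raise ValueError(f"unknown reduction {reduction!r}")

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-z))
        dz = (s - t) * scale
        if warr is not None:
            dz = dz * warr
        logits._accum(g * dz)

    return Tensor._make(out_data, (logits,), backward, logits.requires_grad)
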