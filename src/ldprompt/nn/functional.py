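"""Spatial operations for (N, C, H, W) tensors: padding, convolution, bilinear
resampling.  Convolution uses im2col + matmul; bilinear resampling is a fixed
linear map applied per axis (align_corners=False convention), so its backward
pass is the transposed map."""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .tensor import Tensor

__all__ = ["pad2d", "conv2d", "bilinear_resize", "global_avg_pool", "pixel_shuffle2"]


def _reflect_indices(n: int, pad: int) -> np.ndarray:
    # reflect without repeating the border sample (numpy "reflect" mode)
    idx = np.arange(-pad, n + pad)
    period = 2 * n - 2 if n > 1 else 1
    idx = np.mod(idx, period)
    idx = np.where(idx >= n, period - idx, idx)
    return idx.astype(np.intp)


def pad2d(x: Tensor, pad: int, mode: str = "zeros") -> Tensor:
    """Pad the two trailing spatial axes by `pad` on each side."""
    if pad == 0:
        return x
    n, c, h, w = x.shape
    if mode == "zeros":
        out_data = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float64)
        out_data[:, :, pad:pad + h, pad:pad + w] = x.data

        def backward(g):
            if x.requires_grad:
                x._accum(g[:, :, pad:pad + h, pad:pad + w])

        out = Tensor(out_data)
    elif mode == "reflect":
        ri = _reflect_indices(h, pad)
        ci = _reflect_indices(w, pad)
        out_data = x.data[:, :, ri, :][:, :, :, ci]

        def backward(g):
            if x.requires_grad:
                # undo the column gather, then the row gather
                g_rows = np.zeros((n, c, h + 2 * pad, w), dtype=np.float64)
                np.add.at(g_rows.transpose(3, 0, 1, 2), ci, g.transpose(3, 0, 1, 2))
                gx = np.zeros_like(x.data)
                np.add.at(gx.transpose(2, 0, 1, 3), ri, g_rows.transpose(2, 0, 1, 3))
                x._accum(gx)

        out = Tensor(out_data)
    else:
        raise ValueError(f"unknown pad mode {mode!r}")
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, pad_mode: str = "zeros") -> Tensor:
    """2-D convolution (cross-correlation) on (N, C, H, W)."""
    x = pad2d(x, padding, pad_mode)
    n, c, h, w = x.shape
    o, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight expects {ci}")
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    cols = win[:, :, ::stride, ::stride, :, :]  # (N, C, Ho, Wo, kh, kw)
    out_data = np.einsum("ncyxab,ocab->noyx", cols, weight.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    def backward(g):
        if weight.requires_grad:
            gw = np.einsum("noyx,ncyxab->ocab", g, cols, optimize=True)
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("noyx,ocab->ncyxab", g, weight.data, optimize=True)
            gx = np.zeros((n, c, h, w), dtype=np.float64)
            for a in range(kh):
                for b in range(kw):
                    gx[:, :, a:a + stride * ho:stride, b:b + stride * wo:stride] += gcols[:, :, :, :, a, b]
            x._accum(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


@lru_cache(maxsize=64)
def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense (n_out, n_in) interpolation matrix, align_corners=False."""
    m = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        m[i, lo_c] += 1.0 - frac
        m[i, hi_c] += frac
    return m


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resampling of (N, C, H, W) to (N, C, out_h, out_w)."""
    n, c, h, w = x.shape
    wr = _bilinear_matrix(out_h, h)
    wc = _bilinear_matrix(out_w, w)
    out_data = np.einsum("ij,ncjk,lk->ncil", wr, x.data, wc, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accum(np.einsum("ij,ncil,lk->ncjk", wr, g, wc, optimize=True))

    out = Tensor(out_data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def pixel_shuffle2(x: Tensor) -> Tensor:
    """(N, 4C, H, W) -> (N, C, 2H, 2W); building block for stride-2
    kernel-2 transposed convolution (per-pixel linear map + shuffle)."""
    n, c4, h, w = x.shape
    c = c4 // 4
    y = x.reshape(n, c, 2, 2, h, w)
    y = y.transpose(0, 1, 4, 2, 5, 3)  # (N, C, H, 2, W, 2)
    return y.reshape(n, c, 2 * h, 2 * w)
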