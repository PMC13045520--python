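"""Spatial primitives: convolution, pooling, bilinear resize and the
directional-field warp used by feature rectification.

All operators take NCHW tensors.  Convolutions are stride-1 (the model only
downsamples through max-pooling and patchification).  The warp treats its
displacement field as a constant during backpropagation: the field is trained
through its own supervision loss, so only the adjoint with respect to the
sampled feature values is needed.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .tensor import Tensor

__all__ = ["conv2d", "max_pool2d", "bilinear_resize", "frf_warp"]


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B,C,H,W) -> (B, C*kh*kw, Ho*Wo) patch matrix for stride-1 windows."""
    b, c, h, w = x.shape
    ho, wo = h - kh + 1, w - kw + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, (b, c, kh, kw, ho, wo), (s0, s1, s2, s3, s2, s3), writeable=False
    )
    return windows.reshape(b, c * kh * kw, ho * wo)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) of NCHW input."""
    b, cin, h, w = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    cols = _im2col(xp, kh, kw)  # (B, Ckk, L)
    w2 = weight.data.reshape(cout, -1)
    out = np.matmul(w2, cols)  # (B, Cout, L)
    ho, wo = h + 2 * padding - kh + 1, w + 2 * padding - kw + 1
    out = out.reshape(b, cout, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)
    req = x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)

    def bwd(g):
        g2 = g.reshape(b, cout, -1)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.data.shape))
        if x.requires_grad:
            # full correlation of the upstream gradient with the flipped kernel
            gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
            gcols = _im2col(gp, kh, kw)
            wf = np.flip(weight.data, axis=(2, 3)).transpose(1, 0, 2, 3).reshape(cin, -1)
            gxp = np.matmul(wf, gcols).reshape(b, cin, h + 2 * padding, w + 2 * padding)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, req, parents, bwd if req else None)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """k×k max pooling with stride k; gradient split evenly across ties."""
    b, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"max_pool2d: spatial dims ({h},{w}) not divisible by {k}")
    ho, wo = h // k, w // k
    xr = x.data.reshape(b, c, ho, k, wo, k)
    out = xr.max(axis=(3, 5))
    req = x.requires_grad

    def bwd(g):
        mask = xr == out[:, :, :, None, :, None]
        count = mask.sum(axis=(3, 5), keepdims=True)
        gx = mask * (g[:, :, :, None, :, None] / count)
        x._accumulate(gx.reshape(b, c, h, w))

    return Tensor(out, req, (x,), bwd if req else None)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D linear interpolation matrix (n_out × n_in), endpoints aligned."""
    mat = np.zeros((n_out, n_in), dtype=np.float32)
    if n_out == 1 or n_in == 1:
        mat[:, 0] = 1.0
        return mat
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    i0 = np.floor(pos).astype(int)
    i0 = np.minimum(i0, n_in - 2)
    frac = (pos - i0).astype(np.float32)
    rows = np.arange(n_out)
    mat[rows, i0] = 1.0 - frac
    mat[rows, i0 + 1] += frac
    return mat


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Separable bilinear resize of an NCHW tensor to ``out_hw``."""
    _, _, h, w = x.data.shape
    ho, wo = out_hw
    ar = _interp_matrix(h, ho)  # (Ho, H)
    ac = _interp_matrix(w, wo)  # (Wo, W)
    out = np.matmul(np.matmul(ar, x.data), ac.T)
    req = x.requires_grad

    def bwd(g):
        x._accumulate(np.matmul(np.matmul(ar.T, g), ac))

    return Tensor(out, req, (x,), bwd if req else None)


def _warp_operator(df: np.ndarray) -> sparse.csr_matrix:
    """Sparse bilinear sampling operator for one displacement field.

    ``df`` is (2, H, W) in (dx, dy) channel order.  Row p of the returned
    (H·W × H·W) matrix holds the bilinear weights of the source location
    (px + dx, py + dy), with out-of-grid coordinates clamped to the border.
    """
    _, h, w = df.shape
    cols_idx, rows_idx = np.meshgrid(np.arange(w), np.arange(h))
    sx = np.clip(cols_idx + df[0].astype(np.float64), 0, w - 1).ravel()
    sy = np.clip(rows_idx + df[1].astype(np.float64), 0, h - 1).ravel()
    x0 = np.floor(sx).astype(int)
    y0 = np.floor(sy).astype(int)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = sx - x0
    fy = sy - y0
    n = h * w
    rows = np.tile(np.arange(n), 4)
    cols = np.concatenate([y0 * w + x0, y0 * w + x1, y1 * w + x0, y1 * w + x1])
    vals = np.concatenate([(1 - fy) * (1 - fx), (1 - fy) * fx, fy * (1 - fx), fy * fx])
    op = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n), dtype=np.float32)
    return op.tocsr()


def frf_warp(x: Tensor, df: np.ndarray, steps: int) -> Tensor:
    """Iterated feature rectification: F^k(p) = F^(k-1)(p + DF(p)), k = 1..steps.

    The same displacement field indexes every step, so the warp is the sparse
    sampling operator applied ``steps`` times.  ``df`` is a (B,2,H,W) array
    (not a Tensor): coordinates are constants under differentiation.
    """
    if steps < 0:
        raise ValueError("rectification step count must be >= 0")
    b, c, h, w = x.data.shape
    if df.shape != (b, 2, h, w):
        raise ValueError(f"df shape {df.shape} does not match features {(b, 2, h, w)}")
    if steps == 0:
        return x
    ops = [_warp_operator(df[i]) for i in range(b)]
    out = np.empty_like(x.data)
    for i in range(b):
        flat = x.data[i].reshape(c, h * w)
        for _ in range(steps):
            flat = flat @ ops[i].T
        out[i] = flat.reshape(c, h, w)
    req = x.requires_grad

    def bwd(g):
        gx = np.empty_like(g)
        for i in range(b):
            flat = g[i].reshape(c, h * w)
            for _ in range(steps):
                flat = flat @ ops[i]
            gx[i] = flat.reshape(c, h, w)
        x._accumulate(gx)

    return Tensor(out, req, (x,), bwd if req else None)
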