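"""Volumetric network primitives: 3D convolution, pooling, upsampling, batch norm.

Convolutions are stride-1, zero-padded to preserve spatial shape ("same"),
with odd kernels (1 or 3) and optional dilation. The forward pass lowers
each convolution to an im2col matrix product; the input gradient is the
correlation of the output gradient with the spatially flipped, channel-
transposed kernel, which reuses the same lowering.

Array layout is ``(N, C, Z, Y, X)`` throughout.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["conv3d", "max_pool3d", "upsample_nearest3d", "batch_norm3d"]


def _pad_spatial(x: np.ndarray, pad: int) -> np.ndarray:
    if not pad:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))


def _tap_view(xp: np.ndarray, shape, tap, dilation: int) -> np.ndarray:
    """The input window aligned with kernel tap (a, b, c)."""
    z, y, x = shape
    a, b, c = tap
    d = dilation
    return xp[:, :, a * d : a * d + z, b * d : b * d + y, c * d : c * d + x]


def _conv_raw(x: np.ndarray, w: np.ndarray, dilation: int) -> np.ndarray:
    """Same-padded stride-1 correlation of (N,C,Z,Y,X) with (O,C,k,k,k).

    Computed as one channel-matmul per kernel tap over a shifted view of
    the padded input; avoids gathering an im2col patch matrix, which is
    the memory-traffic bottleneck for small channel counts.
    """
    k = w.shape[-1]
    n, c, z, y, xx = x.shape
    o = w.shape[0]
    if k == 1:
        out = np.matmul(w.reshape(o, c), x.reshape(n, c, -1))
        return out.reshape(n, o, z, y, xx)
    xp = _pad_spatial(x, dilation * (k - 1) // 2)
    acc = np.zeros((o, n, z, y, xx), dtype=x.dtype)
    for a in range(k):
        for b in range(k):
            for cc in range(k):
                sub = _tap_view(xp, (z, y, xx), (a, b, cc), dilation)
                acc += np.tensordot(w[:, :, a, b, cc], sub, axes=([1], [1]))
    return np.ascontiguousarray(acc.transpose(1, 0, 2, 3, 4))


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """3D convolution with "same" zero padding.

    Parameters
    ----------
    x : Tensor, shape (N, C_in, Z, Y, X)
    w : Tensor, shape (C_out, C_in, k, k, k) with k odd (1 or 3)
    b : Tensor or None, shape (C_out,)
    dilation : int
        Dilation rate applied along all three spatial axes.
    """
    k = w.shape[-1]
    out_data = _conv_raw(x.data, w.data, dilation)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    req = any(p.requires_grad for p in parents)
    out = Tensor(out_data, req, parents)

    if req:
        def bwd(g: np.ndarray) -> None:
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3, 4)))
            if w.requires_grad:
                if k == 1:
                    dw = np.tensordot(g, x.data, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
                    w._accumulate(dw.reshape(w.shape))
                else:
                    xp = _pad_spatial(x.data, dilation * (k - 1) // 2)
                    dw = np.empty_like(w.data)
                    for ka in range(k):
                        for kb in range(k):
                            for kc in range(k):
                                sub = _tap_view(xp, g.shape[2:], (ka, kb, kc), dilation)
                                dw[:, :, ka, kb, kc] = np.tensordot(
                                    g, sub, axes=([0, 2, 3, 4], [0, 2, 3, 4])
                                )
                    w._accumulate(dw)
            if x.requires_grad:
                # input gradient = same-padded correlation with the
                # spatially flipped kernel, in/out channels swapped
                wt = np.ascontiguousarray(
                    w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
                )
                x._accumulate(_conv_raw(g, wt, dilation))

        out._backward = bwd
    return out


def max_pool3d(x: Tensor, factor: tuple[int, int, int]) -> Tensor:
    """Non-overlapping max pooling; spatial dims must be divisible by `factor`."""
    fz, fy, fx = factor
    n, c, z, y, xx = x.shape
    if z % fz or y % fy or xx % fx:
        raise ValueError(
            f"input shape {(z, y, xx)} not divisible by pooling factor {factor}"
        )
    oz, oy, ox = z // fz, y // fy, xx // fx
    r = (
        x.data.reshape(n, c, oz, fz, oy, fy, ox, fx)
        .transpose(0, 1, 2, 4, 6, 3, 5, 7)
        .reshape(n, c, oz, oy, ox, fz * fy * fx)
    )
    idx = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, x.requires_grad, (x,))

    if x.requires_grad:
        def bwd(g: np.ndarray) -> None:
            grid = np.zeros((n, c, oz, oy, ox, fz * fy * fx), dtype=g.dtype)
            np.put_along_axis(grid, idx[..., None], g[..., None], axis=-1)
            gx = (
                grid.reshape(n, c, oz, oy, ox, fz, fy, fx)
                .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                .reshape(n, c, z, y, xx)
            )
            x._accumulate(gx)

        out._backward = bwd
    return out


def upsample_nearest3d(x: Tensor, factor: tuple[int, int, int]) -> Tensor:
    """Nearest-neighbour upsampling by integer factors per axis."""
    fz, fy, fx = factor
    d = x.data
    if fz > 1:
        d = np.repeat(d, fz, axis=2)
    if fy > 1:
        d = np.repeat(d, fy, axis=3)
    if fx > 1:
        d = np.repeat(d, fx, axis=4)
    out = Tensor(d, x.requires_grad, (x,))

    if x.requires_grad:
        n, c, z, y, xx = x.shape

        def bwd(g: np.ndarray) -> None:
            gx = g.reshape(n, c, z, fz, y, fy, xx, fx).sum(axis=(3, 5, 7))
            x._accumulate(gx)

        out._backward = bwd
    return out


def batch_norm3d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, Z, Y, X).

    Running statistics are updated in place when `training` is true.
    """
    axes = (0, 2, 3, 4)
    shape = (1, x.shape[1], 1, 1, 1)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * inv_std.reshape(shape)
    out_data = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    parents = (x, gamma, beta)
    req = any(p.requires_grad for p in parents)
    out = Tensor(out_data, req, parents)

    if req:
        m = x.data.size / x.shape[1]  # samples per channel

        def bwd(g: np.ndarray) -> None:
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if x.requires_grad:
                gs = gamma.data.reshape(shape) * inv_std.reshape(shape)
                if training:
                    gmean = g.mean(axis=axes, keepdims=True)
                    gxhat = (g * xhat).mean(axis=axes, keepdims=True)
                    x._accumulate(gs * (g - gmean - xhat * gxhat))
                else:
                    x._accumulate(gs * g)

        out._backward = bwd
    return out
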