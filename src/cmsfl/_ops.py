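"""Low-level array operations with hand-written backward passes.

Everything here works on NCHW float arrays and is written so that forward
calls optionally return the cache needed by the matching backward call.
Convolution is expressed as nine shifted slab GEMMs (one per kernel tap):
each tap multiplies a contiguous view of the padded input by its (F, C)
weight slice and accumulates into a width-padded output, so the whole
operation runs through BLAS with no im2col gather and no patch buffer.
"""

from __future__ import annotations

import numpy as np

BN_EPS = 1e-5
BN_MOMENTUM = 0.1


def conv3x3_forward(x: np.ndarray, weights: np.ndarray, want_cache: bool = True):
    """3x3 convolution, stride 1, padding 1, no bias.

    x: (N, C, H, W); weights: (F, C, 3, 3) -> (N, F, H, W).
    """
    n, c, h, w = x.shape
    f = weights.shape[0]
    if weights.shape[1] != c:
        raise ValueError(
            f"channel mismatch: expected {weights.shape[1]} input channels, got {c}"
        )
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    y = np.zeros((n, f, h, w), dtype=np.result_type(x, weights))
    k = h * (w + 2)
    for i in range(3):
        slab = xp[:, :, i : i + h, :].reshape(n, c, k)  # contiguous view
        for j in range(3):
            # tap (i, j): (F, C) @ (N, C, K) -> (N, F, H, W+2), shifted add
            tmp = np.matmul(weights[:, :, i, j], slab).reshape(n, f, h, w + 2)
            y += tmp[:, :, :, j : j + w]
    cache = (xp, weights) if want_cache else None
    return y, cache


def conv3x3_backward(dy: np.ndarray, cache):
    xp, weights = cache
    n, c = xp.shape[0], xp.shape[1]
    h, w = xp.shape[2] - 2, xp.shape[3] - 2
    f = weights.shape[0]
    dy_flat = dy.reshape(n, f, h * w)
    dxp = np.zeros_like(xp)
    dw = np.empty_like(weights)
    # dy embedded at the three possible column shifts, reused across i
    dyz = np.zeros((3, n, f, h, w + 2), dtype=dy.dtype)
    for j in range(3):
        dyz[j, :, :, :, j : j + w] = dy
    k = h * (w + 2)
    for i in range(3):
        slab = xp[:, :, i : i + h, :].reshape(n, c, k)
        for j in range(3):
            # data gradient: (C, F) @ (N, F, H*W) scattered at shift (i, j)
            g = np.matmul(weights[:, :, i, j].T, dy_flat).reshape(n, c, h, w)
            dxp[:, :, i : i + h, j : j + w] += g
            # weight gradient: contract dy (embedded at shift j) with slab i
            dz = dyz[j].reshape(n, f, k)
            dw[:, :, i, j] = np.matmul(dz, slab.transpose(0, 2, 1)).sum(axis=0)
    return dxp[:, :, 1:-1, 1:-1], dw


def conv3x3_bruteforce(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Nested-loop reference convolution (test oracle; O(N F C H W 9))."""
    n, c, h, w = x.shape
    f = weights.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    y = np.zeros((n, f, h, w), dtype=np.result_type(x, weights))
    for ni in range(n):
        for fi in range(f):
            for hi in range(h):
                for wi in range(w):
                    acc = 0.0
                    for ci in range(c):
                        for di in range(3):
                            for dj in range(3):
                                acc += (
                                    weights[fi, ci, di, dj]
                                    * xp[ni, ci, hi + di, wi + dj]
                                )
                    y[ni, fi, hi, wi] = acc
    return y


def bn_forward(x, gain, bias, running_mean, running_var, mode, want_cache=True):
    """Per-channel batch normalization on (N, C, H, W).

    Train mode normalizes with batch statistics and updates the running
    buffers in place (momentum 0.1); eval mode uses the running buffers.
    """
    if mode == "train":
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running_mean *= 1.0 - BN_MOMENTUM
        running_mean += BN_MOMENTUM * mean
        running_var *= 1.0 - BN_MOMENTUM
        running_var += BN_MOMENTUM * np.maximum(var, BN_EPS)
    elif mode == "eval":
        mean, var = running_mean, running_var
    else:
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    inv_sd = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (x - mean[None, :, None, None]) * inv_sd[None, :, None, None]
    y = xhat * gain[None, :, None, None] + bias[None, :, None, None]
    cache = (xhat, inv_sd, gain, mode) if want_cache else None
    return y, cache


def bn_backward(dy, cache):
    xhat, inv_sd, gain, mode = cache
    m = dy.shape[0] * dy.shape[2] * dy.shape[3]
    dgain = (dy * xhat).sum(axis=(0, 2, 3))
    dbias = dy.sum(axis=(0, 2, 3))
    dxhat = dy * gain[None, :, None, None]
    if mode == "eval":
        dx = dxhat * inv_sd[None, :, None, None]
    else:
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        ) * inv_sd[None, :, None, None]
    return dx, dgain, dbias


def relu_forward(x, want_cache=True):
    y = np.maximum(x, 0.0)
    return y, ((x > 0) if want_cache else None)


def relu_backward(dy, cache):
    return dy * cache


def maxpool2x2_forward(x, want_cache=True):
    """2x2 max pooling with stride 2; H and W must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool requires even spatial dims, got {h}x{w}")
    win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    arg = win.argmax(axis=-1)
    y = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
    cache = (arg, x.shape) if want_cache else None
    return y, cache


def maxpool2x2_backward(dy, cache):
    arg, shape = cache
    n, c, h, w = shape
    dwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dwin, arg[..., None], dy[..., None], axis=-1)
    dwin = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dwin.reshape(n, c, h, w)


def dense_forward(x, weight, want_cache=True):
    """Bias-free dense layer: (N, D) @ (J, D)^T -> (N, J)."""
    y = x @ weight.T
    return y, ((x, weight) if want_cache else None)


def dense_backward(dy, cache):
    x, weight = cache
    return dy @ weight, dy.T @ x


def cosine_head_forward(x, class_vectors, scale, want_cache=True):
    """Scaled-cosine class scores: scale * cos(feature, class_vector).

    x: (N, D); class_vectors: (J, D); scale: scalar. Both the features and
    the class vectors are l2-normalized, so the score depends only on angle.
    """
    xn = np.linalg.norm(x, axis=1, keepdims=True)
    wn = np.linalg.norm(class_vectors, axis=1, keepdims=True)
    if np.any(wn == 0):
        raise ValueError("cosine head has a zero class vector")
    xn = np.maximum(xn, 1e-12)
    u = x / xn
    v = class_vectors / wn
    cos = u @ v.T
    y = scale * cos
    cache = (u, v, xn, wn, cos, scale) if want_cache else None
    return y, cache


def cosine_head_backward(dy, cache):
    u, v, xn, wn, cos, scale = cache
    dscale = float((dy * cos).sum())
    dcos = dy * scale
    # d cos_nc / dx_n = (v_c - cos_nc * u_n) / |x_n|
    dx = (dcos @ v - (dcos * cos).sum(axis=1, keepdims=True) * u) / xn
    dv = dcos.T @ u - (dcos * cos).sum(axis=0)[:, None] * v
    dw = dv / wn
    return dx, dw, dscale
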