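"""Low-level 3D network ops (forward + backward) in NumPy.

Tensors are channel-first float32: ``(B, C, D, H, W)``.  Convolutions are
computed by looping over the kernel offsets — each offset contributes one
strided slice contracted against a ``(C_out, C_in)`` weight slab via BLAS —
which keeps memory flat (no im2col buffer) and is fast at patch sizes in
the tens of voxels per axis.  Every backward here is checked against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv3d_forward",
    "conv3d_backward",
    "convtranspose3d_forward",
    "convtranspose3d_backward",
    "batchnorm_forward",
    "batchnorm_backward",
    "relu_forward",
    "relu_backward",
    "sigmoid_forward",
    "sigmoid_backward",
]


def _triple(v):
    if np.isscalar(v):
        return (int(v),) * 3
    return tuple(int(x) for x in v)


def conv3d_forward(x, w, b, stride=1, pad=0):
    """3D cross-correlation.  ``w``: (F, C, kd, kh, kw); returns (B, F, *out)."""
    s = _triple(stride)
    p = _triple(pad)
    B, C, D, H, W = x.shape
    F = w.shape[0]
    kd, kh, kw = w.shape[2:]
    xp = np.pad(x, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
    Do = (D + 2 * p[0] - kd) // s[0] + 1
    Ho = (H + 2 * p[1] - kh) // s[1] + 1
    Wo = (W + 2 * p[2] - kw) // s[2] + 1
    y = np.zeros((B, F, Do, Ho, Wo), dtype=x.dtype)
    for i in range(kd):
        for j in range(kh):
            for l in range(kw):
                xs = xp[
                    :, :, i : i + s[0] * Do : s[0], j : j + s[1] * Ho : s[1], l : l + s[2] * Wo : s[2]
                ]
                # (B,C,P) x (F,C) -> (B,F,P)
                y += np.tensordot(xs, w[:, :, i, j, l], axes=([1], [1])).transpose(0, 4, 1, 2, 3)
    if b is not None:
        y += b.reshape(1, F, 1, 1, 1)
    return y


def conv3d_backward(x, w, gy, stride=1, pad=0):
    """Gradients of :func:`conv3d_forward` w.r.t. input, weights and bias."""
    s = _triple(stride)
    p = _triple(pad)
    B, C, D, H, W = x.shape
    F = w.shape[0]
    kd, kh, kw = w.shape[2:]
    Do, Ho, Wo = gy.shape[2:]
    xp = np.pad(x, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
    gxp = np.zeros_like(xp)
    gw = np.zeros_like(w)
    for i in range(kd):
        for j in range(kh):
            for l in range(kw):
                sl = (
                    slice(None),
                    slice(None),
                    slice(i, i + s[0] * Do, s[0]),
                    slice(j, j + s[1] * Ho, s[1]),
                    slice(l, l + s[2] * Wo, s[2]),
                )
                xs = xp[sl]
                gw[:, :, i, j, l] = np.tensordot(gy, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
                gxp[sl] += np.tensordot(gy, w[:, :, i, j, l], axes=([1], [0])).transpose(
                    0, 4, 1, 2, 3
                )
    gb = gy.sum(axis=(0, 2, 3, 4))
    gx = gxp[:, :, p[0] : p[0] + D, p[1] : p[1] + H, p[2] : p[2] + W]
    return np.ascontiguousarray(gx), gw, gb


def convtranspose3d_forward(x, w, b, stride=2, pad=1):
    """Transposed 3D convolution.  ``w``: (C_in, F, kd, kh, kw).

    Output spatial size is ``stride * (n - 1) + k - 2 * pad`` per axis
    (with the default 4/2/1 setup: exactly double).
    """
    s = _triple(stride)
    p = _triple(pad)
    B, C, D, H, W = x.shape
    F = w.shape[1]
    kd, kh, kw = w.shape[2:]
    full = (s[0] * (D - 1) + kd, s[1] * (H - 1) + kh, s[2] * (W - 1) + kw)
    yf = np.zeros((B, F, *full), dtype=x.dtype)
    for i in range(kd):
        for j in range(kh):
            for l in range(kw):
                contrib = np.tensordot(x, w[:, :, i, j, l], axes=([1], [0])).transpose(
                    0, 4, 1, 2, 3
                )
                yf[
                    :, :, i : i + s[0] * D : s[0], j : j + s[1] * H : s[1], l : l + s[2] * W : s[2]
                ] += contrib
    y = yf[
        :,
        :,
        p[0] : full[0] - p[0],
        p[1] : full[1] - p[1],
        p[2] : full[2] - p[2],
    ]
    if b is not None:
        y = y + b.reshape(1, F, 1, 1, 1)
    return np.ascontiguousarray(y)


def convtranspose3d_backward(x, w, gy, stride=2, pad=1):
    """Gradients of :func:`convtranspose3d_forward`."""
    s = _triple(stride)
    p = _triple(pad)
    B, C, D, H, W = x.shape
    kd, kh, kw = w.shape[2:]
    full = (s[0] * (D - 1) + kd, s[1] * (H - 1) + kh, s[2] * (W - 1) + kw)
    gyf = np.zeros((B, w.shape[1], *full), dtype=gy.dtype)
    gyf[
        :,
        :,
        p[0] : full[0] - p[0],
        p[1] : full[1] - p[1],
        p[2] : full[2] - p[2],
    ] = gy
    gx = np.zeros_like(x)
    gw = np.zeros_like(w)
    for i in range(kd):
        for j in range(kh):
            for l in range(kw):
                gys = gyf[
                    :, :, i : i + s[0] * D : s[0], j : j + s[1] * H : s[1], l : l + s[2] * W : s[2]
                ]
                gx += np.tensordot(gys, w[:, :, i, j, l], axes=([1], [1])).transpose(0, 4, 1, 2, 3)
                gw[:, :, i, j, l] = np.tensordot(x, gys, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
    gb = gy.sum(axis=(0, 2, 3, 4))
    return gx, gw, gb


def batchnorm_forward(x, gamma, beta, running_mean, running_var, training, momentum=0.1, eps=1e-5):
    """Per-channel batch normalization over (batch, spatial) axes.

    Returns ``(y, cache)``; in training mode the running statistics are
    updated in place.
    """
    axes = (0, 2, 3, 4)
    if training:
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    shape = (1, -1, 1, 1, 1)
    xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
    y = gamma.reshape(shape) * xhat + beta.reshape(shape)
    cache = (xhat, inv_std, gamma, training)
    return y.astype(x.dtype), cache


def batchnorm_backward(gy, cache):
    xhat, inv_std, gamma, training = cache
    shape = (1, -1, 1, 1, 1)
    axes = (0, 2, 3, 4)
    ggamma = (gy * xhat).sum(axis=axes)
    gbeta = gy.sum(axis=axes)
    gxhat = gy * gamma.reshape(shape)
    if not training:
        return gxhat * inv_std.reshape(shape), ggamma, gbeta
    n = gy.size / gy.shape[1]
    gx = (
        inv_std.reshape(shape)
        / n
        * (n * gxhat - gxhat.sum(axis=axes).reshape(shape) - xhat * ggamma.reshape(shape))
    )
    return gx.astype(gy.dtype), ggamma, gbeta


def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(gy, mask):
    return gy * mask


def sigmoid_forward(x):
    # numerically stable logistic
    y = np.empty_like(x)
    pos = x >= 0
    y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    y[~pos] = ex / (1.0 + ex)
    return y


def sigmoid_backward(gy, y):
    return gy * y * (1.0 - y)
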