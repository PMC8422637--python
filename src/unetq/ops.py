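"""Dense 3D tensor primitives shared by the float reference path and the toy
fitting helper.

All functions operate on 5-axis arrays (batch, channel, depth, height, width).
Convolutions are direct (offset-accumulation) rather than FFT-based: at the
volume sizes this package targets the direct form is fast enough, exact for
integer dtypes, and trivially auditable against a nested-loop oracle.

Deconvolution (transposed convolution) is realized constructively as
zero-insertion upsampling followed by an ordinary convolution with the
spatially flipped kernel — the same construction the hardware model uses,
which is why deconvolution outputs contain the large zero fraction the
zero-block-skipping optimization exploits.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError
from .layers import Triple


def pad3d(x: np.ndarray, padding: Triple) -> np.ndarray:
    pd, ph, pw = padding
    if pd == ph == pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))


def conv_out_shape(spatial: Triple, kernel: Triple, stride: Triple, padding: Triple) -> Triple:
    out = tuple(
        (n + 2 * p - k) // s + 1 for n, k, s, p in zip(spatial, kernel, stride, padding)
    )
    if any(o < 1 for o in out):
        raise ShapeError(
            f"spatial {spatial} too small for kernel {kernel} / stride {stride} / "
            f"padding {padding}"
        )
    return out


def conv3d(x: np.ndarray, w: np.ndarray, stride: Triple = (1, 1, 1),
           padding: Triple = (0, 0, 0)) -> np.ndarray:
    """Direct 3D cross-correlation. Integer inputs accumulate in int64."""
    if x.ndim != 5 or w.ndim != 5:
        raise ShapeError("conv3d expects 5-axis input and weights")
    if x.shape[1] != w.shape[1]:
        raise ShapeError(
            f"input has {x.shape[1]} channels but kernel expects {w.shape[1]}"
        )
    kd, kh, kw = w.shape[2:5]
    sd, sh, sw = stride
    Do, Ho, Wo = conv_out_shape(x.shape[2:5], (kd, kh, kw), stride, padding)
    xp = pad3d(x, padding)
    integer = np.issubdtype(x.dtype, np.integer)
    dtype = np.int64 if integer else np.result_type(x.dtype, w.dtype, np.float64)
    out = np.zeros((x.shape[0], w.shape[0], Do, Ho, Wo), dtype=dtype)
    wa = w.astype(dtype, copy=False)
    for dz in range(kd):
        for dy in range(kh):
            for dx in range(kw):
                xs = xp[:, :, dz:dz + sd * Do:sd, dy:dy + sh * Ho:sh, dx:dx + sw * Wo:sw]
                out += np.einsum("oc,bczyx->bozyx", wa[:, :, dz, dy, dx],
                                 xs.astype(dtype, copy=False))
    return out


def zero_insert(x: np.ndarray, stride: Triple) -> np.ndarray:
    """Insert stride-1 zeros between voxels along each spatial axis."""
    sd, sh, sw = stride
    if sd == sh == sw == 1:
        return x
    b, c, D, H, W = x.shape
    out = np.zeros((b, c, (D - 1) * sd + 1, (H - 1) * sh + 1, (W - 1) * sw + 1),
                   dtype=x.dtype)
    out[:, :, ::sd, ::sh, ::sw] = x
    return out


def flip_kernel(w: np.ndarray) -> np.ndarray:
    return w[:, :, ::-1, ::-1, ::-1]


def deconv3d(x: np.ndarray, w: np.ndarray, stride: Triple = (2, 2, 2),
             padding: Triple = (0, 0, 0)) -> np.ndarray:
    """Transposed 3D convolution via zero-insertion + flipped-kernel conv.

    Output spatial size is (n-1)*stride + kernel - 2*padding per axis; with
    kernel 2, stride 2, padding 0 each axis exactly doubles.
    """
    k = w.shape[2:5]
    pads = tuple(ki - 1 - pi for ki, pi in zip(k, padding))
    if any(p < 0 for p in pads):
        raise ShapeError("transposed conv requires padding <= kernel - 1")
    return conv3d(zero_insert(x, stride), flip_kernel(w), (1, 1, 1), pads)


def conv3d_backward(x: np.ndarray, w: np.ndarray, gy: np.ndarray,
                    stride: Triple, padding: Triple):
    """Gradients of conv3d wrt input, weights and bias."""
    kd, kh, kw = w.shape[2:5]
    sd, sh, sw = stride
    pd, ph, pw = padding
    b, c, D, H, W = x.shape
    Do, Ho, Wo = gy.shape[2:5]
    xp = pad3d(x.astype(np.float64, copy=False), padding)
    gxp = np.zeros_like(xp)
    gw = np.zeros(w.shape, dtype=np.float64)
    for dz in range(kd):
        for dy in range(kh):
            for dx in range(kw):
                sl = (slice(None), slice(None),
                      slice(dz, dz + sd * Do, sd),
                      slice(dy, dy + sh * Ho, sh),
                      slice(dx, dx + sw * Wo, sw))
                gw[:, :, dz, dy, dx] = np.einsum("bozyx,bczyx->oc", gy, xp[sl])
                gxp[sl] += np.einsum("oc,bozyx->bczyx", w[:, :, dz, dy, dx], gy)
    gx = gxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W]
    gb = gy.sum(axis=(0, 2, 3, 4))
    return gx, gw, gb


def deconv3d_backward(x: np.ndarray, w: np.ndarray, gy: np.ndarray,
                      stride: Triple, padding: Triple):
    """Gradients of deconv3d, reusing conv3d_backward on the construction."""
    k = w.shape[2:5]
    pads = tuple(ki - 1 - pi for ki, pi in zip(k, padding))
    xz = zero_insert(x, stride)
    gxz, gwf, gb = conv3d_backward(xz, flip_kernel(w), gy, (1, 1, 1), pads)
    sd, sh, sw = stride
    gx = gxz[:, :, ::sd, ::sh, ::sw]
    return gx, flip_kernel(gwf), gb


def batchnorm(x: np.ndarray, mean, var, gamma, beta, eps: float) -> np.ndarray:
    shp = (1, -1, 1, 1, 1)
    scale = gamma / np.sqrt(var + eps)
    return x * scale.reshape(shp) + (beta - mean * scale).reshape(shp)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def maxpool2(x: np.ndarray) -> np.ndarray:
    """2x2x2 max pooling with stride 2 (spatial axes must be even)."""
    b, c, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ShapeError(f"maxpool2 needs even spatial axes, got {(D, H, W)}")
    v = x.reshape(b, c, D // 2, 2, H // 2, 2, W // 2, 2)
    return v.max(axis=(3, 5, 7))


def maxpool2_backward(x: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Route gradients to the (first) argmax voxel of each 2x2x2 cell."""
    b, c, D, H, W = x.shape
    v = (x.reshape(b, c, D // 2, 2, H // 2, 2, W // 2, 2)
         .transpose(0, 1, 2, 4, 6, 3, 5, 7)
         .reshape(b, c, D // 2, H // 2, W // 2, 8))
    idx = v.argmax(axis=-1)[..., None]
    g = np.zeros_like(v, dtype=np.float64)
    np.put_along_axis(g, idx, gy[..., None], axis=-1)
    return (g.reshape(b, c, D // 2, H // 2, W // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(b, c, D, H, W))
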