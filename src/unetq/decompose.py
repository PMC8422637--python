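"""3D convolution realized as accumulated 2D convolutions over depth slices.

The hardware computes 3D convolutions with a 2D processing-element array: a
k_d x k_h x k_w kernel is split into k_d separate k_h x k_w kernels, one per
depth offset, and the 3D result is the accumulation of the k_d intermediate
2D results.  For integer inputs the decomposition is exact — integer addition
is associative — so the decomposed path is bit-identical to direct 3D
convolution.  The int8 inference engine routes all of its convolutions
through this module.

Accumulation is depth-slice-major: slice 0 is fully accumulated over the
whole output before slice 1 starts, mirroring the accelerator's per-block
accumulation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError
from .layers import Triple
from .ops import conv_out_shape, flip_kernel, pad3d, zero_insert


@dataclass
class SliceKernelSet:
    """A 3D kernel viewed as one 2D kernel per depth offset."""

    slices: list[np.ndarray]  # each (out_ch, in_ch, kh, kw)
    depth_offsets: list[int]

    def __post_init__(self) -> None:
        if len(self.slices) != len(self.depth_offsets):
            raise ShapeError("one depth offset per kernel slice required")

    @property
    def kd(self) -> int:
        return len(self.slices)

    def reassemble(self) -> np.ndarray:
        """Stack the 2D slices back into the original 5-axis kernel."""
        return np.stack(self.slices, axis=2)


def decompose_kernel(k3d: np.ndarray) -> SliceKernelSet:
    """Split a (out_ch, in_ch, kd, kh, kw) kernel into kd 2D kernels."""
    if k3d.ndim != 5:
        raise ShapeError("expected a 5-axis kernel (o, c, kd, kh, kw)")
    kd = k3d.shape[2]
    return SliceKernelSet(
        slices=[np.ascontiguousarray(k3d[:, :, i, :, :]) for i in range(kd)],
        depth_offsets=list(range(kd)),
    )


def _conv2d_planes(xz: np.ndarray, k2: np.ndarray, stride_hw, out_hw,
                   dtype) -> np.ndarray:
    """2D convolution applied independently to every depth plane.

    ``xz`` is (b, c, Do, Hp, Wp): for each output depth index the matching
    (already selected) input plane.  No height/width padding is applied here;
    the caller pads the full volume once.
    """
    sh, sw = stride_hw
    Ho, Wo = out_hw
    kh, kw = k2.shape[2:4]
    out = np.zeros((xz.shape[0], k2.shape[0], xz.shape[2], Ho, Wo), dtype=dtype)
    k2a = k2.astype(dtype, copy=False)
    for dy in range(kh):
        for dx in range(kw):
            xs = xz[:, :, :, dy:dy + sh * Ho:sh, dx:dx + sw * Wo:sw]
            out += np.einsum("oc,bczyx->bozyx", k2a[:, :, dy, dx],
                             xs.astype(dtype, copy=False))
    return out


def conv3d_via_2d(x: np.ndarray, ks: SliceKernelSet, stride: Triple = (1, 1, 1),
                  padding: Triple = (0, 0, 0)) -> np.ndarray:
    """3D convolution as a depth-slice-major accumulation of 2D convolutions.

    Bit-exact for integer inputs (int64 accumulation); within float rounding
    of the direct form otherwise.
    """
    if x.ndim != 5:
        raise ShapeError("conv3d_via_2d expects a 5-axis input")
    if x.shape[1] != ks.slices[0].shape[1]:
        raise ShapeError(
            f"input has {x.shape[1]} channels but kernel expects "
            f"{ks.slices[0].shape[1]}"
        )
    kh, kw = ks.slices[0].shape[2:4]
    kernel = (ks.kd, kh, kw)
    sd, sh, sw = stride
    Do, Ho, Wo = conv_out_shape(x.shape[2:5], kernel, stride, padding)
    xp = pad3d(x, padding)
    integer = np.issubdtype(x.dtype, np.integer)
    dtype = np.int64 if integer else np.result_type(x.dtype, np.float64)
    out = np.zeros((x.shape[0], ks.slices[0].shape[0], Do, Ho, Wo), dtype=dtype)
    for k2, off in zip(ks.slices, ks.depth_offsets):
        xz = xp[:, :, off:off + sd * Do:sd]  # one input plane per output depth
        out += _conv2d_planes(xz, k2, (sh, sw), (Ho, Wo), dtype)
    return out


def deconv3d_via_2d(x: np.ndarray, w: np.ndarray, stride: Triple = (2, 2, 2),
                    padding: Triple = (0, 0, 0)) -> np.ndarray:
    """Transposed convolution through the decomposed path:
    zero-insertion upsampling, then decomposed convolution with the flipped
    kernel."""
    k = w.shape[2:5]
    pads = tuple(ki - 1 - pi for ki, pi in zip(k, padding))
    if any(p < 0 for p in pads):
        raise ShapeError("transposed conv requires padding <= kernel - 1")
    return conv3d_via_2d(zero_insert(x, stride), decompose_kernel(flip_kernel(w)),
                         (1, 1, 1), pads)
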