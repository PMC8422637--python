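"""3D U-Net graph construction and the float reference inference path.

The topology follows the standard encoder/decoder layout: an analysis path of
conv–BN–ReLU blocks with 2x2x2 max-pooling between resolution levels, and a
synthesis path that upsamples with stride-2 deconvolutions and concatenates
the skip connection from the matching encoder level (skip channels first).
Channel counts double per level; a 1x1x1 convolution maps the first-level
features to per-class scores.

The float path defined here is the ground truth every quantized, decomposed
and scheduled computation in the package is validated against.
"""

from __future__ import annotations

import numpy as np

from . import ops
from .errors import GraphError, ShapeError
from .layers import BNParams, ConvParams, Layer, NetworkGraph, Volume


def _zero_conv(out_ch: int, in_ch: int, kernel, stride=(1, 1, 1),
               padding=(0, 0, 0), transposed=False) -> ConvParams:
    k = (kernel, kernel, kernel) if isinstance(kernel, int) else kernel
    return ConvParams(
        weights=np.zeros((out_ch, in_ch, *k), dtype=np.float64),
        bias=np.zeros(out_ch, dtype=np.float64),
        stride=stride, padding=padding, transposed=transposed,
    )


def _identity_bn(ch: int) -> BNParams:
    return BNParams(mean=np.zeros(ch), var=np.ones(ch),
                    gamma=np.ones(ch), beta=np.zeros(ch))


def build_unet3d(channels_base: int, depth_levels: int, in_channels: int,
                 out_classes: int) -> NetworkGraph:
    """Construct a 3D U-Net graph with zero-initialized parameters.

    ``depth_levels`` is the number of resolution levels: level ``i`` works at
    1/2**i of the input resolution with ``channels_base * 2**i`` channels.
    With ``channels_base=32, in_channels=4`` the first conv maps 4 -> 32
    channels, the canonical first-level width of the brain-segmentation
    3D U-Net.
    """
    if channels_base < 1 or depth_levels < 1 or in_channels < 1 or out_classes < 1:
        raise GraphError("channels_base, depth_levels, in_channels and "
                         "out_classes must all be >= 1")
    layers: list[Layer] = []

    def add(name, op, inputs, conv=None, bn=None) -> str:
        layers.append(Layer(name=name, op=op, inputs=list(inputs), conv=conv, bn=bn))
        return name

    def conv_block(tag: str, prev: str, in_ch: int, out_ch: int) -> str:
        prev = add(f"{tag}_conv", "conv", [prev],
                   conv=_zero_conv(out_ch, in_ch, 3, padding=(1, 1, 1)))
        prev = add(f"{tag}_bn", "bn", [prev], bn=_identity_bn(out_ch))
        return add(f"{tag}_relu", "relu", [prev])

    level_ch = [channels_base * 2 ** i for i in range(depth_levels)]
    skips: list[str] = []
    prev = "input"
    prev_ch = in_channels
    for lvl in range(depth_levels):
        c = level_ch[lvl]
        prev = conv_block(f"enc{lvl}a", prev, prev_ch, c)
        prev = conv_block(f"enc{lvl}b", prev, c, c)
        skips.append(prev)
        prev_ch = c
        if lvl < depth_levels - 1:
            prev = add(f"pool{lvl}", "maxpool", [prev])
    for lvl in range(depth_levels - 2, -1, -1):
        c = level_ch[lvl]
        prev = add(f"dec{lvl}_up", "deconv", [prev],
                   conv=_zero_conv(c, prev_ch, 2, stride=(2, 2, 2), transposed=True))
        prev = add(f"dec{lvl}_up_bn", "bn", [prev], bn=_identity_bn(c))
        prev = add(f"dec{lvl}_up_relu", "relu", [prev])
        prev = add(f"dec{lvl}_concat", "concat", [skips[lvl], prev])
        prev = conv_block(f"dec{lvl}a", prev, 2 * c, c)
        prev = conv_block(f"dec{lvl}b", prev, c, c)
        prev_ch = c
    add("classifier", "classifier", [prev],
        conv=_zero_conv(out_classes, prev_ch, 1))
    return NetworkGraph(layers=layers, in_channels=in_channels,
                        out_classes=out_classes, depth_levels=depth_levels)


def _layer_forward(lay: Layer, xs: list[np.ndarray]) -> np.ndarray:
    try:
        if lay.op in ("conv", "classifier"):
            return (ops.conv3d(xs[0], lay.conv.weights, lay.conv.stride,
                               lay.conv.padding)
                    + lay.conv.bias.reshape(1, -1, 1, 1, 1))
        if lay.op == "deconv":
            return (ops.deconv3d(xs[0], lay.conv.weights, lay.conv.stride,
                                 lay.conv.padding)
                    + lay.conv.bias.reshape(1, -1, 1, 1, 1))
        if lay.op == "bn":
            b = lay.bn
            return ops.batchnorm(xs[0], b.mean, b.var, b.gamma, b.beta, b.eps)
        if lay.op == "relu":
            return ops.relu(xs[0])
        if lay.op == "maxpool":
            return ops.maxpool2(xs[0])
        if lay.op == "concat":
            if xs[0].shape[2:] != xs[1].shape[2:]:
                raise ShapeError(
                    f"concat branches have spatial shapes {xs[0].shape[2:]} "
                    f"and {xs[1].shape[2:]}"
                )
            return np.concatenate(xs, axis=1)
    except ShapeError as exc:
        raise ShapeError(f"layer {lay.name!r}: {exc}") from None
    raise GraphError(f"layer {lay.name!r}: unknown op {lay.op!r}")


def forward_activations(net: NetworkGraph, x: np.ndarray) -> dict[str, np.ndarray]:
    """Run the float network, returning every layer's output keyed by name."""
    if x.ndim != 5:
        raise ShapeError("network input must have 5 axes")
    if x.shape[1] != net.in_channels:
        raise ShapeError(
            f"network expects {net.in_channels} input channels, got {x.shape[1]}"
        )
    div = 2 ** (net.depth_levels - 1)
    if any(a % div for a in x.shape[2:5]):
        raise ShapeError(
            f"spatial axes {x.shape[2:5]} must be divisible by {div} "
            f"(2**(depth_levels-1))"
        )
    acts: dict[str, np.ndarray] = {"input": x}
    for lay in net.layers:
        acts[lay.name] = _layer_forward(lay, [acts[s] for s in lay.inputs])
    return acts


def infer_float(net: NetworkGraph, v: Volume) -> Volume:
    """Float reference inference: per-class score volume (classifier output)."""
    if v.value_kind != "real":
        raise ShapeError("infer_float requires a real-valued volume")
    acts = forward_activations(net, np.asarray(v.data, dtype=np.float64))
    return Volume(data=acts[net.layers[-1].name], value_kind="real",
                  affine=v.affine)


def argmax_labels(scores: Volume) -> Volume:
    """Per-voxel argmax over the channel axis; ties go to the lowest class."""
    lab = np.argmax(scores.data, axis=1, keepdims=True).astype(np.int16)
    return Volume(data=lab, value_kind="real", affine=scores.affine)
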