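"""Domain types: layer parameter records, layer graph nodes and volumes.

Axis convention is fixed everywhere as (batch, channel, depth, height, width).
Convolution weights are stored (out_ch, in_ch, kd, kh, kw) for both ordinary
and transposed (deconvolution) layers.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .errors import GraphError, ShapeError

Triple = tuple[int, int, int]

#: Canonical order in which the four MRI modalities are stacked on the
#: channel axis when a case is assembled from single-modality files.
MODALITIES = ("flair", "t1", "t2", "t1ce")

#: Layer ops that carry convolution parameters.
PARAM_OPS = ("conv", "deconv", "classifier")


def _triple(v) -> Triple:
    if isinstance(v, int):
        return (v, v, v)
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ShapeError(f"expected an int or length-3 tuple, got {v!r}")
    return t


@dataclass
class ConvParams:
    """Parameters of a 3D convolution or deconvolution (transposed conv)."""

    weights: np.ndarray  # (out_ch, in_ch, kd, kh, kw)
    bias: np.ndarray  # (out_ch,)
    stride: Triple = (1, 1, 1)
    padding: Triple = (0, 0, 0)
    transposed: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        self.bias = np.asarray(self.bias)
        self.stride = _triple(self.stride)
        self.padding = _triple(self.padding)
        if self.weights.ndim != 5:
            raise ShapeError("conv weights must have 5 axes (o, c, kd, kh, kw)")
        if any(k < 1 for k in self.kernel):
            raise ShapeError("kernel extents must be >= 1")
        if self.bias.shape != (self.out_channels,):
            raise ShapeError("bias length must equal out_channels")
        if any(s < 1 for s in self.stride):
            raise ShapeError("stride components must be >= 1")
        if any(p < 0 for p in self.padding):
            raise ShapeError("padding components must be >= 0")
        if self.transposed and any(
            k - 1 - p < 0 for k, p in zip(self.kernel, self.padding)
        ):
            raise ShapeError("transposed conv requires padding <= kernel - 1")

    @property
    def out_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def in_channels(self) -> int:
        return self.weights.shape[1]

    @property
    def kernel(self) -> Triple:
        return tuple(self.weights.shape[2:5])


@dataclass
class BNParams:
    """Inference-time batch-normalization statistics and affine parameters."""

    mean: np.ndarray
    var: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    eps: float = 1e-5

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        n = self.mean.shape
        if not (self.var.shape == n and self.gamma.shape == n and self.beta.shape == n):
            raise ShapeError("BN parameter vectors must all have the same length")
        if np.any(self.var < 0):
            raise ShapeError("BN variance must be non-negative")
        if not self.eps > 0:
            raise ShapeError("BN epsilon must be positive")

    @property
    def channels(self) -> int:
        return self.mean.shape[0]


@dataclass
class Layer:
    """One node of the network graph.

    ``op`` is one of conv | deconv | classifier | bn | relu | maxpool | concat.
    ``inputs`` are names of predecessor layers ("input" refers to the network
    input).  Concat lists the skip connection first, then the upsampled branch.
    """

    name: str
    op: str
    inputs: list[str]
    conv: ConvParams | None = None
    bn: BNParams | None = None

    def __post_init__(self) -> None:
        if self.op in PARAM_OPS and self.conv is None:
            raise GraphError(f"layer {self.name!r}: op {self.op!r} needs ConvParams")
        if self.op == "bn" and self.bn is None:
            raise GraphError(f"layer {self.name!r}: op 'bn' needs BNParams")
        if self.op == "concat" and len(self.inputs) != 2:
            raise GraphError(f"layer {self.name!r}: concat needs exactly 2 inputs")
        if self.op != "concat" and len(self.inputs) != 1:
            raise GraphError(f"layer {self.name!r}: op {self.op!r} needs 1 input")


@dataclass
class NetworkGraph:
    """Ordered, acyclic layer graph of a 3D U-Net-style network.

    ``layers`` is a topological order: every layer's inputs appear earlier in
    the list (or are the network input).  The last layer is the classifier
    head whose channel count is the number of output classes.
    """

    layers: list[Layer]
    in_channels: int
    out_classes: int
    depth_levels: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def layer(self, name: str) -> Layer:
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise GraphError(f"no layer named {name!r}")

    def validate(self) -> None:
        seen: dict[str, int] = {}
        for lay in self.layers:
            if lay.name in seen or lay.name == "input":
                raise GraphError(f"duplicate layer name {lay.name!r}")
            for src in lay.inputs:
                if src != "input" and src not in seen:
                    raise GraphError(
                        f"layer {lay.name!r} consumes {src!r} before it is defined"
                    )
            seen[lay.name] = 1
        # channel agreement along every edge
        for lay, ch_in in self._edge_channels():
            if lay.op in PARAM_OPS and lay.conv.in_channels != ch_in:
                raise GraphError(
                    f"layer {lay.name!r}: expects {lay.conv.in_channels} input "
                    f"channels, receives {ch_in}"
                )
            if lay.op == "bn" and lay.bn.channels != ch_in:
                raise GraphError(
                    f"layer {lay.name!r}: BN over {lay.bn.channels} channels, "
                    f"receives {ch_in}"
                )

    def _edge_channels(self):
        """Yield (layer, input_channel_count) pairs by forward propagation."""
        ch = {"input": self.in_channels}
        for lay in self.layers:
            cin = sum(ch[src] for src in lay.inputs)
            yield lay, cin if lay.op == "concat" else ch[lay.inputs[0]]
            if lay.op in PARAM_OPS:
                ch[lay.name] = lay.conv.out_channels
            elif lay.op == "concat":
                ch[lay.name] = cin
            else:
                ch[lay.name] = ch[lay.inputs[0]]

    def channels(self) -> dict[str, int]:
        """Output channel count of every layer (and of "input")."""
        ch = {"input": self.in_channels}
        for lay in self.layers:
            if lay.op in PARAM_OPS:
                ch[lay.name] = lay.conv.out_channels
            elif lay.op == "concat":
                ch[lay.name] = sum(ch[s] for s in lay.inputs)
            else:
                ch[lay.name] = ch[lay.inputs[0]]
        return ch

    def copy(self) -> "NetworkGraph":
        return copy.deepcopy(self)


@dataclass
class Volume:
    """A 5-axis voxel tensor: (batch, channel, depth, height, width).

    ``value_kind`` is "real" for floating-point intensities/scores and
    "int8-code" for quantized codes, in which case ``shift_bits`` records the
    power-of-two scale (real value = code * 2**-shift_bits).
    """

    data: np.ndarray
    value_kind: str = "real"
    shift_bits: int | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ShapeError(
                f"volume must have 5 axes (b, c, d, h, w), got {self.data.ndim}"
            )
        if any(a < 1 for a in self.data.shape):
            raise ShapeError("all volume axes must be >= 1")
        if self.value_kind not in ("real", "int8-code"):
            raise ShapeError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == "int8-code":
            if self.shift_bits is None:
                raise ShapeError("int8-code volumes must carry shift_bits")
            if self.data.min() < -128 or self.data.max() > 127:
                raise ShapeError("int8-code values must lie in [-128, 127]")
        elif self.shift_bits is not None:
            raise ShapeError("real volumes must not carry shift_bits")

    @property
    def spatial(self) -> Triple:
        return tuple(self.data.shape[2:5])

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]
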