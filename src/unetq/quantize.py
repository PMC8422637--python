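"""Dynamic fixed-point int8 quantization and the bit-exact integer engine.

Every tensor (weights, biases, activations) is represented by 8-bit signed
codes together with a power-of-two scale factor 2**b_s, so that

    real value  ~=  code * 2**(-b_s).

The shift-bit count is chosen from the tensor's maximum absolute value:

    b_s = b_w - 1 - ceil(log2(max_abs))        (b_w = 8)

which places the largest magnitude just inside the [-128, 127] code range
(an exact power of two lands on 128 and saturates to 127; this follows the
scale rule literally and is accepted).  Scaling by 2**b_s is a bit shift on
hardware, which is the reason for the power-of-two constraint.

Weight and bias scale factors are computed separately per convolutional or
deconvolutional layer; activation scale factors come from a calibration pass
that records per-layer max absolute input/output over a small set of
calibration volumes run through the *float* (BN-folded) network.

The integer engine mirrors the FPGA arithmetic: int8 x int8 products
accumulate in a 32-bit signed accumulator at scale b_s(weight)+b_s(input);
the int8 bias is shifted to the accumulator scale before addition; the
accumulator is then rescaled to the layer's output scheme by an arithmetic
shift with round-half-away-from-zero and clamped back to [-128, 127].
ReLU is max(0, code) and max-pooling is an integer max, both scale-preserving.
The result is bit-reproducible across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import decompose, ops
from .errors import (AccumulatorOverflow, CalibrationError, GraphError,
                     QuantizationError, ShapeError)
from .layers import PARAM_OPS, NetworkGraph, Triple, Volume
from .metrics import dice, pixel_accuracy
from .network import argmax_labels, forward_activations, infer_float

INT32_MAX = 2 ** 31 - 1


# ---------------------------------------------------------------------------
# schemes and elementwise quantization


@dataclass(frozen=True)
class QuantScheme:
    """An 8-bit signed fixed-point representation with scale 2**shift_bits."""

    shift_bits: int
    bit_width: int = 8

    @property
    def scale(self) -> float:
        return 2.0 ** self.shift_bits


def shift_bits(max_abs: float, bit_width: int = 8) -> int:
    """Shift-bit count for a tensor with the given max absolute value.

    For an all-zero tensor any scale is exact; bit_width - 1 is used so that
    log2(0) never arises.
    """
    if not math.isfinite(max_abs) or max_abs < 0:
        raise QuantizationError(f"max_abs must be finite and >= 0, got {max_abs}")
    if max_abs == 0:
        return bit_width - 1
    return bit_width - 1 - math.ceil(math.log2(max_abs))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest with ties away from zero (the hardware idiom)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantize_tensor(t: np.ndarray, scheme: QuantScheme, name: str = "tensor") -> np.ndarray:
    """Map a real tensor to int8 codes: clamp(round(x * 2**b_s), -128, 127)."""
    if scheme.bit_width != 8:
        raise QuantizationError("only 8-bit schemes are supported")
    t = np.asarray(t, dtype=np.float64)
    if not np.all(np.isfinite(t)):
        raise QuantizationError(f"{name} contains non-finite values")
    q = _round_half_away(t * scheme.scale)
    return np.clip(q, -128, 127).astype(np.int8)


def dequantize(codes: np.ndarray, scheme: QuantScheme) -> np.ndarray:
    return codes.astype(np.float64) * 2.0 ** (-scheme.shift_bits)


def rshift_round(v: np.ndarray, s: int) -> np.ndarray:
    """Arithmetic right shift by s >= 0 with round-half-away-from-zero."""
    if s == 0:
        return v
    off = np.int64(1) << (s - 1)
    a = np.abs(v)
    return np.where(v >= 0, (a + off) >> s, -((a + off) >> s))


def rescale_codes(v: np.ndarray, from_bits: int, to_bits: int,
                  clamp: bool = True) -> np.ndarray:
    """Move integer codes from scale 2**from_bits to 2**to_bits."""
    v = v.astype(np.int64, copy=False)
    d = to_bits - from_bits
    out = v << d if d >= 0 else rshift_round(v, -d)
    if clamp:
        out = np.clip(out, -128, 127)
    return out


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationRecord:
    """Per-layer max absolute float input/output over calibration volumes."""

    input_max: float  # max |x| of the network input itself
    layer_stats: dict[str, tuple[float, float]]  # name -> (max_in, max_out)
    n_volumes: int = 0

    def merge(self, other: "CalibrationRecord") -> "CalibrationRecord":
        stats = {
            k: (max(self.layer_stats[k][0], other.layer_stats[k][0]),
                max(self.layer_stats[k][1], other.layer_stats[k][1]))
            for k in self.layer_stats
        }
        return CalibrationRecord(
            input_max=max(self.input_max, other.input_max),
            layer_stats=stats,
            n_volumes=self.n_volumes + other.n_volumes,
        )


def _check_folded(net: NetworkGraph) -> None:
    if any(lay.op == "bn" for lay in net.layers):
        raise GraphError("network still contains BN layers; fold it first "
                         "(folding.fold_network)")


def calibrate(net: NetworkGraph, calib: list[Volume]) -> CalibrationRecord:
    """Record per-layer activation ranges by running the float network.

    Emulates the paper's calibration: a small set of volumes (two patient
    cases in the original study) is run forward in float and the running max
    absolute value of every (de)convolutional layer's input and output is
    kept.
    """
    _check_folded(net)
    if not calib:
        raise CalibrationError("calibration set must not be empty")
    record: CalibrationRecord | None = None
    for v in calib:
        if v.value_kind != "real":
            raise CalibrationError("calibration volumes must be real-valued")
        x = np.asarray(v.data, dtype=np.float64)
        acts = forward_activations(net, x)
        stats = {}
        for lay in net.layers:
            if lay.op in PARAM_OPS:
                xin = np.concatenate([acts[s] for s in lay.inputs], axis=1)
                stats[lay.name] = (float(np.abs(xin).max()),
                                   float(np.abs(acts[lay.name]).max()))
        rec = CalibrationRecord(input_max=float(np.abs(x).max()),
                                layer_stats=stats, n_volumes=1)
        record = rec if record is None else record.merge(rec)
    return record


# ---------------------------------------------------------------------------
# quantized network


@dataclass
class QuantizedLayer:
    """An int8 conv/deconv layer with its four per-tensor schemes."""

    name: str
    op: str  # conv | deconv | classifier
    inputs: list[str]
    weights: np.ndarray  # int8, (out_ch, in_ch, kd, kh, kw)
    bias: np.ndarray  # int8, (out_ch,)
    weight_scheme: QuantScheme
    bias_scheme: QuantScheme
    input_scheme: QuantScheme
    output_scheme: QuantScheme
    stride: Triple = (1, 1, 1)
    padding: Triple = (0, 0, 0)
    transposed: bool = False

    @property
    def out_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def in_channels(self) -> int:
        return self.weights.shape[1]

    @property
    def kernel(self) -> Triple:
        return tuple(self.weights.shape[2:5])

    @property
    def acc_shift(self) -> int:
        """Shift bits of the accumulator scale (weight b_s + input b_s)."""
        return self.weight_scheme.shift_bits + self.input_scheme.shift_bits


@dataclass
class QPlainLayer:
    """A non-parametric layer (relu / maxpool / concat) with its schemes."""

    name: str
    op: str
    inputs: list[str]
    input_scheme: QuantScheme
    output_scheme: QuantScheme


@dataclass
class QuantizedNetwork:
    layers: list  # QuantizedLayer | QPlainLayer, topological order
    in_channels: int
    out_classes: int
    depth_levels: int
    input_scheme: QuantScheme

    def layer(self, name: str):
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise GraphError(f"no layer named {name!r}")

    def scheme_manifest(self) -> dict[str, dict[str, int]]:
        """layer name -> tensor role -> shift bits; round-trips the archive."""
        man: dict[str, dict[str, int]] = {
            "__input__": {"input": self.input_scheme.shift_bits}
        }
        for lay in self.layers:
            entry = {"input": lay.input_scheme.shift_bits,
                     "output": lay.output_scheme.shift_bits}
            if isinstance(lay, QuantizedLayer):
                entry["weight"] = lay.weight_scheme.shift_bits
                entry["bias"] = lay.bias_scheme.shift_bits
            man[lay.name] = entry
        return man


def quantize_network(net: NetworkGraph, record: CalibrationRecord) -> QuantizedNetwork:
    """Quantize a BN-folded float network using calibrated activation ranges.

    Weight and bias schemes are computed per layer from the parameter
    tensors themselves; input/output schemes come from the calibration
    record.  Schemes of non-parametric layers are derived: ReLU and pooling
    preserve their input scheme, concatenation requantizes both branches to
    the coarser (smaller shift) scheme.
    """
    _check_folded(net)
    in_scheme = QuantScheme(shift_bits(record.input_max))
    scheme_of: dict[str, QuantScheme] = {"input": in_scheme}
    qlayers: list = []
    for lay in net.layers:
        if lay.op in PARAM_OPS:
            if lay.name not in record.layer_stats:
                raise CalibrationError(
                    f"calibration record has no entry for layer {lay.name!r}"
                )
            max_in, max_out = record.layer_stats[lay.name]
            ws = QuantScheme(shift_bits(float(np.abs(lay.conv.weights).max())))
            bs = QuantScheme(shift_bits(float(np.abs(lay.conv.bias).max())))
            s_in = QuantScheme(shift_bits(max_in))
            s_out = QuantScheme(shift_bits(max_out))
            qlayers.append(QuantizedLayer(
                name=lay.name, op=lay.op, inputs=list(lay.inputs),
                weights=quantize_tensor(lay.conv.weights, ws,
                                        f"{lay.name}.weights"),
                bias=quantize_tensor(lay.conv.bias, bs, f"{lay.name}.bias"),
                weight_scheme=ws, bias_scheme=bs,
                input_scheme=s_in, output_scheme=s_out,
                stride=lay.conv.stride, padding=lay.conv.padding,
                transposed=lay.conv.transposed,
            ))
            scheme_of[lay.name] = s_out
        else:
            if lay.op == "concat":
                s = QuantScheme(min(scheme_of[x].shift_bits for x in lay.inputs))
            else:
                s = scheme_of[lay.inputs[0]]
            qlayers.append(QPlainLayer(
                name=lay.name, op=lay.op, inputs=list(lay.inputs),
                input_scheme=scheme_of[lay.inputs[0]], output_scheme=s,
            ))
            scheme_of[lay.name] = s
    return QuantizedNetwork(layers=qlayers, in_channels=net.in_channels,
                            out_classes=net.out_classes,
                            depth_levels=net.depth_levels,
                            input_scheme=in_scheme)


def quantize_volume(v: Volume, qnet: QuantizedNetwork) -> Volume:
    """Quantize a real volume to the network's input scheme."""
    codes = quantize_tensor(v.data, qnet.input_scheme, "input volume")
    return Volume(data=codes, value_kind="int8-code",
                  shift_bits=qnet.input_scheme.shift_bits, affine=v.affine)


# ---------------------------------------------------------------------------
# integer inference


def effective_conv(ql: QuantizedLayer):
    """The ordinary convolution equivalent of a (de)conv layer.

    Returns (kernel int8 array, stride, padding, pre-op) where pre-op maps
    the layer's input codes to the effective input: identity for ordinary
    convolution, zero-insertion for transposed convolution (whose kernel is
    also spatially flipped).  The accelerator model partitions this
    effective convolution.
    """
    if ql.transposed:
        pads = tuple(k - 1 - p for k, p in zip(ql.kernel, ql.padding))
        return (ops.flip_kernel(ql.weights), (1, 1, 1), pads,
                lambda x: ops.zero_insert(x, ql.stride))
    return ql.weights, ql.stride, ql.padding, lambda x: x


def aligned_bias(ql: QuantizedLayer) -> np.ndarray:
    """Bias codes shifted from the bias scheme to the accumulator scale."""
    return rescale_codes(ql.bias.astype(np.int64), ql.bias_scheme.shift_bits,
                         ql.acc_shift, clamp=False)


def finish_accumulator(acc: np.ndarray, ql: QuantizedLayer) -> np.ndarray:
    """Add the aligned bias, check the 32-bit range, rescale and clamp."""
    acc = acc + aligned_bias(ql).reshape(1, -1, 1, 1, 1)
    if np.abs(acc).max(initial=0) > INT32_MAX:
        raise AccumulatorOverflow(
            f"layer {ql.name!r}: accumulator exceeds 32-bit signed range"
        )
    out = rescale_codes(acc, ql.acc_shift, ql.output_scheme.shift_bits)
    return out.astype(np.int8)


def _conv_int8(ql: QuantizedLayer, x_codes: np.ndarray) -> np.ndarray:
    w, stride, padding, pre = effective_conv(ql)
    xe = pre(x_codes.astype(np.int64))
    acc = decompose.conv3d_via_2d(xe, decompose.decompose_kernel(w),
                                  stride, padding)
    return finish_accumulator(acc, ql)


def infer_int8_activations(qnet: QuantizedNetwork, x_codes: np.ndarray
                           ) -> dict[str, np.ndarray]:
    """Integer-only forward pass; per-layer int8 codes keyed by layer name."""
    if x_codes.dtype != np.int8:
        raise ShapeError("expected int8 codes as network input")
    acts: dict[str, np.ndarray] = {"input": x_codes}
    scheme_of: dict[str, QuantScheme] = {"input": qnet.input_scheme}
    for lay in qnet.layers:
        xs = [acts[s] for s in lay.inputs]
        if isinstance(lay, QuantizedLayer):
            x = rescale_codes(xs[0], scheme_of[lay.inputs[0]].shift_bits,
                              lay.input_scheme.shift_bits).astype(np.int8)
            acts[lay.name] = _conv_int8(lay, x)
        elif lay.op == "relu":
            acts[lay.name] = np.maximum(xs[0], 0)
        elif lay.op == "maxpool":
            acts[lay.name] = ops.maxpool2(xs[0])
        elif lay.op == "concat":
            t = lay.output_scheme.shift_bits
            parts = [
                rescale_codes(x, scheme_of[s].shift_bits, t).astype(np.int8)
                for x, s in zip(xs, lay.inputs)
            ]
            acts[lay.name] = np.concatenate(parts, axis=1)
        else:
            raise GraphError(f"layer {lay.name!r}: unknown op {lay.op!r}")
        scheme_of[lay.name] = lay.output_scheme
    return acts


def infer_int8(qnet: QuantizedNetwork, v: Volume) -> Volume:
    """Bit-exact int8 inference; returns the classifier's code volume."""
    if v.value_kind != "int8-code":
        raise ShapeError("infer_int8 requires an int8-code volume "
                         "(use quantize_volume)")
    if v.shift_bits != qnet.input_scheme.shift_bits:
        raise ShapeError(
            f"input volume scheme (b_s={v.shift_bits}) does not match the "
            f"network input scheme (b_s={qnet.input_scheme.shift_bits})"
        )
    acts = infer_int8_activations(qnet, np.asarray(v.data, dtype=np.int8))
    last = qnet.layers[-1]
    return Volume(data=acts[last.name], value_kind="int8-code",
                  shift_bits=last.output_scheme.shift_bits, affine=v.affine)


# ---------------------------------------------------------------------------
# float vs int8 comparison


def compare_float_int8(net: NetworkGraph, qnet: QuantizedNetwork,
                       volumes: list[Volume],
                       references: list[Volume] | None = None,
                       class_id: int = 1) -> pd.DataFrame:
    """Per-volume DSC/ACC of the float and int8 paths, plus their deltas.

    If no reference segmentations are given the float path's label maps act
    as the reference, so the table then reports pure quantization agreement.
    """
    rows = []
    for i, v in enumerate(volumes):
        lab_f = argmax_labels(infer_float(net, v)).data
        lab_q = argmax_labels(infer_int8(qnet, quantize_volume(v, qnet))).data
        ref = lab_f if references is None else np.asarray(references[i].data)
        rows.append({
            "volume": i,
            "dsc_float": dice(lab_f, ref, class_id),
            "dsc_int8": dice(lab_q, ref, class_id),
            "acc_float": pixel_accuracy(lab_f, ref),
            "acc_int8": pixel_accuracy(lab_q, ref),
        })
    df = pd.DataFrame(rows)
    df["delta_dsc"] = df["dsc_int8"] - df["dsc_float"]
    df["delta_acc"] = df["acc_int8"] - df["acc_float"]
    return df
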