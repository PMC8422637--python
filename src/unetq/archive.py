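"""Network archives: documented array-archive files with bit-exact round-trip.

An archive is a NumPy ``.npz`` file holding one array per parameter tensor
plus a JSON manifest (stored under the key ``__manifest__``) that lists the
layer order, layer types, hyperparameters and a SHA-256 digest of every
array's raw bytes.  Digests are verified on load, so truncation or bit
corruption is detected rather than silently propagated.

Two archive kinds share the container:

* kind "float"     — float64 weights/biases plus BN statistics;
* kind "quantized" — int8 parameter arrays plus the scheme manifest
  (per-layer shift bits for weight / bias / input / output).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .errors import ArchiveError
from .layers import PARAM_OPS, BNParams, ConvParams, Layer, NetworkGraph
from .quantize import (QPlainLayer, QuantizedLayer, QuantizedNetwork,
                       QuantScheme)

FORMAT_VERSION = 1


def _digest(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()


def _pack(path, manifest: dict, arrays: dict[str, np.ndarray]) -> None:
    manifest = dict(manifest, version=FORMAT_VERSION,
                    digests={k: _digest(v) for k, v in arrays.items()})
    np.savez(path, __manifest__=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **arrays)


def _unpack(path):
    try:
        npz = np.load(path)
    except Exception as exc:  # zipfile/pickle errors -> archive error
        raise ArchiveError(f"cannot read archive {path}: {exc}") from exc
    if "__manifest__" not in npz:
        raise ArchiveError(f"{path}: not a network archive (no manifest)")
    manifest = json.loads(bytes(npz["__manifest__"]).decode())
    if manifest.get("version") != FORMAT_VERSION:
        raise ArchiveError(f"{path}: unsupported archive version")
    arrays = {k: npz[k] for k in npz.files if k != "__manifest__"}
    for k, d in manifest.get("digests", {}).items():
        if k not in arrays:
            raise ArchiveError(f"{path}: missing array {k!r}")
        if _digest(arrays[k]) != d:
            raise ArchiveError(f"{path}: digest mismatch for array {k!r}")
    return manifest, arrays


def save_network(net: NetworkGraph, path) -> None:
    arrays: dict[str, np.ndarray] = {}
    layers = []
    for lay in net.layers:
        rec: dict = {"name": lay.name, "op": lay.op, "inputs": lay.inputs}
        if lay.op in PARAM_OPS:
            arrays[f"{lay.name}/weights"] = lay.conv.weights
            arrays[f"{lay.name}/bias"] = lay.conv.bias
            rec |= {"stride": lay.conv.stride, "padding": lay.conv.padding,
                    "transposed": lay.conv.transposed}
        elif lay.op == "bn":
            for part in ("mean", "var", "gamma", "beta"):
                arrays[f"{lay.name}/{part}"] = getattr(lay.bn, part)
            rec["eps"] = lay.bn.eps
        layers.append(rec)
    _pack(path, {"kind": "float", "layers": layers,
                 "in_channels": net.in_channels, "out_classes": net.out_classes,
                 "depth_levels": net.depth_levels}, arrays)


def load_network(path) -> NetworkGraph:
    manifest, arrays = _unpack(path)
    if manifest.get("kind") != "float":
        raise ArchiveError(f"{path}: expected a float network archive, "
                           f"found kind {manifest.get('kind')!r}")
    layers = []
    for rec in manifest["layers"]:
        name, op = rec["name"], rec["op"]
        conv = bn = None
        if op in PARAM_OPS:
            conv = ConvParams(
                weights=arrays[f"{name}/weights"], bias=arrays[f"{name}/bias"],
                stride=tuple(rec["stride"]), padding=tuple(rec["padding"]),
                transposed=rec["transposed"])
        elif op == "bn":
            bn = BNParams(mean=arrays[f"{name}/mean"], var=arrays[f"{name}/var"],
                          gamma=arrays[f"{name}/gamma"],
                          beta=arrays[f"{name}/beta"],
                          eps=rec.get("eps", 1e-5))
        layers.append(Layer(name=name, op=op, inputs=list(rec["inputs"]),
                            conv=conv, bn=bn))
    return NetworkGraph(layers=layers, in_channels=manifest["in_channels"],
                        out_classes=manifest["out_classes"],
                        depth_levels=manifest["depth_levels"])


def save_quantized(qnet: QuantizedNetwork, path) -> None:
    arrays: dict[str, np.ndarray] = {}
    layers = []
    for lay in qnet.layers:
        rec: dict = {"name": lay.name, "op": lay.op, "inputs": lay.inputs,
                     "schemes": {"input": lay.input_scheme.shift_bits,
                                 "output": lay.output_scheme.shift_bits}}
        if isinstance(lay, QuantizedLayer):
            arrays[f"{lay.name}/weights"] = lay.weights
            arrays[f"{lay.name}/bias"] = lay.bias
            rec["schemes"] |= {"weight": lay.weight_scheme.shift_bits,
                               "bias": lay.bias_scheme.shift_bits}
            rec |= {"stride": lay.stride, "padding": lay.padding,
                    "transposed": lay.transposed}
        layers.append(rec)
    _pack(path, {"kind": "quantized", "layers": layers,
                 "in_channels": qnet.in_channels,
                 "out_classes": qnet.out_classes,
                 "depth_levels": qnet.depth_levels,
                 "input_shift_bits": qnet.input_scheme.shift_bits}, arrays)


def load_quantized(path) -> QuantizedNetwork:
    manifest, arrays = _unpack(path)
    if manifest.get("kind") != "quantized":
        raise ArchiveError(f"{path}: expected a quantized network archive, "
                           f"found kind {manifest.get('kind')!r}")
    layers: list = []
    for rec in manifest["layers"]:
        name, op, sch = rec["name"], rec["op"], rec["schemes"]
        if op in PARAM_OPS:
            layers.append(QuantizedLayer(
                name=name, op=op, inputs=list(rec["inputs"]),
                weights=arrays[f"{name}/weights"].astype(np.int8),
                bias=arrays[f"{name}/bias"].astype(np.int8),
                weight_scheme=QuantScheme(sch["weight"]),
                bias_scheme=QuantScheme(sch["bias"]),
                input_scheme=QuantScheme(sch["input"]),
                output_scheme=QuantScheme(sch["output"]),
                stride=tuple(rec["stride"]), padding=tuple(rec["padding"]),
                transposed=rec["transposed"]))
        else:
            layers.append(QPlainLayer(
                name=name, op=op, inputs=list(rec["inputs"]),
                input_scheme=QuantScheme(sch["input"]),
                output_scheme=QuantScheme(sch["output"])))
    return QuantizedNetwork(layers=layers, in_channels=manifest["in_channels"],
                            out_classes=manifest["out_classes"],
                            depth_levels=manifest["depth_levels"],
                            input_scheme=QuantScheme(manifest["input_shift_bits"]))


def roundtrip_archive(path) -> bool:
    """Read, rewrite and re-read an archive; True iff bit-identical.

    Works for both archive kinds; digests guard each read.
    """
    import tempfile

    manifest, arrays = _unpack(path)
    with tempfile.TemporaryDirectory() as td:
        tmp = Path(td) / "roundtrip.npz"
        if manifest["kind"] == "float":
            save_network(load_network(path), tmp)
        else:
            save_quantized(load_quantized(path), tmp)
        manifest2, arrays2 = _unpack(tmp)
    if set(arrays) != set(arrays2):
        return False
    return all(
        arrays[k].dtype == arrays2[k].dtype
        and np.array_equal(arrays[k], arrays2[k]) for k in arrays
    )
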