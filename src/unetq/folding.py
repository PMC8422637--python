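"""Merging batch-normalization layers into the preceding (de)convolution.

At inference time a BN layer is a per-channel affine map

    y = gamma * (x - mu) / sqrt(var + eps) + beta

applied to the output ``x = W*v + B`` of a convolution.  Composing the two
gives a single convolution with

    W_merged = W * gamma / sqrt(var + eps)
    B_merged = (B - mu) * gamma / sqrt(var + eps) + beta

per output channel.  The ``+ beta`` term is required for the folded layer to
reproduce conv-then-BN exactly; the equivalence is enforced by tests.  The
same rule applies verbatim to deconvolution layers, whose core computation
is the same linear map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GraphError, ShapeError
from .layers import PARAM_OPS, BNParams, ConvParams, Layer, NetworkGraph


@dataclass
class FoldedConv:
    """Merged convolution parameters; shapes equal the source ConvParams."""

    weights: np.ndarray
    bias: np.ndarray


def fold_bn(conv: ConvParams, bn: BNParams) -> FoldedConv:
    """Fold BN statistics into convolution weights and bias."""
    if bn.channels != conv.out_channels:
        raise ShapeError(
            f"BN over {bn.channels} channels cannot fold into a conv with "
            f"{conv.out_channels} output channels"
        )
    scale = bn.gamma / np.sqrt(bn.var + bn.eps)  # per output channel
    w = conv.weights * scale.reshape(-1, 1, 1, 1, 1)
    b = (conv.bias - bn.mean) * scale + bn.beta
    return FoldedConv(weights=w, bias=b)


def fold_network(net: NetworkGraph) -> NetworkGraph:
    """Return an equivalent graph with every BN layer merged away.

    Every BN layer must be immediately preceded by exactly one conv or deconv
    layer; anything else is a structural error, never a silent skip.  Graphs
    without BN layers are returned unchanged (as a copy), which also makes
    the operation idempotent.
    """
    out = net.copy()
    by_name = {lay.name: lay for lay in out.layers}
    consumers: dict[str, int] = {}
    for lay in out.layers:
        for s in lay.inputs:
            consumers[s] = consumers.get(s, 0) + 1
    folded: list[Layer] = []
    renamed: dict[str, str] = {}  # bn layer name -> surviving conv name
    for lay in out.layers:
        lay.inputs = [renamed.get(s, s) for s in lay.inputs]
        if lay.op != "bn":
            folded.append(lay)
            continue
        src = by_name.get(lay.inputs[0])
        if (src is None or src.op not in PARAM_OPS
                or src.name in renamed.values() or consumers[src.name] != 1):
            raise GraphError(
                f"BN layer {lay.name!r} is not immediately preceded by a "
                f"dedicated conv/deconv layer"
            )
        merged = fold_bn(src.conv, lay.bn)
        src.conv = ConvParams(
            weights=merged.weights, bias=merged.bias, stride=src.conv.stride,
            padding=src.conv.padding, transposed=src.conv.transposed,
        )
        renamed[lay.name] = src.name
    return NetworkGraph(layers=folded, in_channels=out.in_channels,
                        out_classes=out.out_classes,
                        depth_levels=out.depth_levels)
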