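import numpy as np
import pytest

from unetq.quantize import (QPlainLayer, QuantizedLayer, QuantizedNetwork,
                            QuantScheme)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_tiny_qnet(rng, *, allow_deconv=True, n_layers=None,
                   allow_pool=False) -> tuple[QuantizedNetwork, np.ndarray]:
    """A random small quantized network plus a matching int8 input volume.

    Shapes, strides, schemes and parameters are all randomized; the volume
    is sized so every layer stays valid.
    """
    n_layers = n_layers or int(rng.integers(1, 4))
    in_ch = int(rng.integers(1, 4))
    spatial = int(rng.choice([4, 6]))
    layers = []
    prev = "input"
    prev_ch = in_ch
    cur_spatial = spatial
    input_scheme = QuantScheme(int(rng.integers(0, 8)))
    prev_scheme = input_scheme
    for i in range(n_layers):
        out_ch = int(rng.integers(1, 4))
        transposed = bool(allow_deconv and cur_spatial <= 6
                          and rng.random() < 0.3)
        if transposed:
            k, stride, padding = 2, (2, 2, 2), (0, 0, 0)
            cur_spatial = cur_spatial * 2
        else:
            k = int(rng.choice([1, 3]))
            stride, padding = (1, 1, 1), (k // 2,) * 3
        w = rng.integers(-128, 128, size=(out_ch, prev_ch, k, k, k),
                         dtype=np.int64).astype(np.int8)
        b = rng.integers(-128, 128, size=out_ch, dtype=np.int64).astype(np.int8)
        out_scheme = QuantScheme(int(rng.integers(-2, 10)))
        lay = QuantizedLayer(
            name=f"conv{i}", op="deconv" if transposed else "conv",
            inputs=[prev], weights=w, bias=b,
            weight_scheme=QuantScheme(int(rng.integers(0, 8))),
            bias_scheme=QuantScheme(int(rng.integers(0, 8))),
            input_scheme=QuantScheme(int(rng.integers(-2, 10))),
            output_scheme=out_scheme,
            stride=stride, padding=padding, transposed=transposed)
        layers.append(lay)
        prev, prev_ch, prev_scheme = lay.name, out_ch, out_scheme
        if rng.random() < 0.5:
            layers.append(QPlainLayer(name=f"relu{i}", op="relu",
                                      inputs=[prev],
                                      input_scheme=prev_scheme,
                                      output_scheme=prev_scheme))
            prev = f"relu{i}"
        if allow_pool and cur_spatial % 2 == 0 and cur_spatial >= 4 \
                and rng.random() < 0.3:
            layers.append(QPlainLayer(name=f"pool{i}", op="maxpool",
                                      inputs=[prev],
                                      input_scheme=prev_scheme,
                                      output_scheme=prev_scheme))
            prev = f"pool{i}"
            cur_spatial //= 2
    qnet = QuantizedNetwork(layers=layers, in_channels=in_ch, out_classes=prev_ch,
                            depth_levels=1, input_scheme=input_scheme)
    x = rng.integers(-128, 128, size=(1, in_ch, spatial, spatial, spatial),
                     dtype=np.int64).astype(np.int8)
    return qnet, x
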