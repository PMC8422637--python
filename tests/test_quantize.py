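"""Shift-bit arithmetic, tensor quantization and the int8 engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from unetq import (GraphError, QuantScheme, ShapeError, Volume, calibrate,
                   fold_network, infer_int8, quantize_network,
                   quantize_tensor, shift_bits)
from unetq.errors import QuantizationError
from unetq.network import forward_activations
from unetq.quantize import (dequantize, infer_int8_activations, rescale_codes,
                            rshift_round)
from unetq.synthetic import PhantomSpec, make_phantom, make_random_network

from .conftest import make_tiny_qnet


@pytest.mark.parametrize("max_abs,expected", [
    (1.0, 7),          # log2(1) = 0
    (3.7, 5),          # ceil(log2 3.7) = 2
    (0.25, 9),         # ceil(log2 0.25) = -2
    (0.0, 7),          # all-zero tensor convention
    (2.0, 6), (128.0, 0), (1024.0, -3), (2.0 ** -10, 17),
])
def test_shift_bits_examples(max_abs, expected):
    assert shift_bits(max_abs, 8) == expected


def test_quantize_zero_maps_to_zero_and_saturation_edge():
    s = QuantScheme(7)
    assert quantize_tensor(np.array([0.0]), s)[0] == 0
    # 1.0 * 2^7 = 128 rounds past the int8 edge and saturates to 127
    assert quantize_tensor(np.array([1.0]), s)[0] == 127
    assert quantize_tensor(np.array([-1.0]), s)[0] == -128


def test_quantize_rejects_non_finite():
    with pytest.raises(QuantizationError, match="weights"):
        quantize_tensor(np.array([np.nan]), QuantScheme(7), "weights")


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 2 ** 32 - 1))
def test_quantization_error_within_half_step(seed):
    """|x - q*2^-b_s| <= 2^(-b_s-1) for every non-saturated element."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(-4, 4, size=64) * 10.0 ** rng.integers(-3, 3)
    bs = shift_bits(float(np.abs(x).max()))
    q = quantize_tensor(x, QuantScheme(bs))
    non_sat = (q > -128) & (q < 127)
    err = np.abs(x - dequantize(q, QuantScheme(bs)))
    assert np.all(err[non_sat] <= 2.0 ** (-bs - 1) + 1e-15)


@settings(derandomize=True, max_examples=50)
@given(st.integers(-(2 ** 30), 2 ** 30), st.integers(0, 12))
def test_right_shift_rounds_half_away_from_zero(v, s):
    """Literal definition: sign(v) * floor(|v| / 2^s + 1/2), in exact
    rational arithmetic."""
    import math
    from fractions import Fraction

    got = rshift_round(np.array([v], dtype=np.int64), s)[0]
    mag = math.floor(Fraction(abs(v), 2 ** s) + Fraction(1, 2))
    assert got == (mag if v >= 0 else -mag)


def _toy_quantized(seed=0):
    net = fold_network(make_random_network(2, 2, seed=seed))
    vols = [make_phantom(PhantomSpec(seed=seed * 10 + i))[0] for i in range(2)]
    rec = calibrate(net, vols)
    return net, rec, quantize_network(net, rec), vols


def test_calibration_is_running_max_of_instrumented_pass():
    net, rec, _, vols = _toy_quantized(seed=4)
    # independent instrumentation of a single volume
    single = calibrate(net, vols[:1])
    acts = forward_activations(net, np.asarray(vols[0].data, float))
    for lay in net.layers:
        if lay.op in ("conv", "deconv", "classifier"):
            mi, mo = single.layer_stats[lay.name]
            assert mi == pytest.approx(np.abs(acts[lay.inputs[0]]).max())
            assert mo == pytest.approx(np.abs(acts[lay.name]).max())
    # two volumes: elementwise max of the single-volume records
    other = calibrate(net, vols[1:])
    for k in rec.layer_stats:
        assert rec.layer_stats[k][0] == max(single.layer_stats[k][0],
                                            other.layer_stats[k][0])
        assert rec.layer_stats[k][1] == max(single.layer_stats[k][1],
                                            other.layer_stats[k][1])


def test_all_zero_volume_calibrates_to_zero_input():
    net = fold_network(make_random_network(1, 1, seed=2, in_channels=2,
                                           out_classes=2))
    z = Volume(data=np.zeros((1, 2, 4, 4, 4)))
    rec = calibrate(net, [z])
    assert rec.input_max == 0.0
    first = net.layers[0].name
    assert rec.layer_stats[first][0] == 0.0


def test_quantize_network_requires_folding_first():
    net = make_random_network(1, 1, seed=3)
    vols = [make_phantom(PhantomSpec(seed=1))[0]]
    with pytest.raises(GraphError, match="fold"):
        calibrate(net, vols)


def test_every_stored_code_in_range_and_unit_weight_scheme():
    net, rec, qnet, _ = _toy_quantized(seed=5)
    for lay in qnet.layers:
        if hasattr(lay, "weights"):
            assert lay.weights.dtype == np.int8
            assert lay.bias.dtype == np.int8
    # a layer whose max |W| is exactly 1.0 gets weight b_s = 7
    lay0 = net.layers[0]
    lay0.conv.weights = lay0.conv.weights / np.abs(lay0.conv.weights).max()
    q2 = quantize_network(net, rec)
    assert q2.layers[0].weight_scheme.shift_bits == 7


def test_identity_conv_int8_passes_codes_through():
    """W code 64 at b_s=6 is weight 1.0: output codes equal input codes."""
    from unetq.quantize import QuantizedLayer, QuantizedNetwork
    lay = QuantizedLayer(
        name="id", op="conv", inputs=["input"],
        weights=np.array([[[[[64]]]]], dtype=np.int8),
        bias=np.zeros(1, dtype=np.int8),
        weight_scheme=QuantScheme(6), bias_scheme=QuantScheme(0),
        input_scheme=QuantScheme(5), output_scheme=QuantScheme(5))
    qnet = QuantizedNetwork(layers=[lay], in_channels=1, out_classes=1,
                            depth_levels=1, input_scheme=QuantScheme(5))
    x = np.arange(-13, 14, dtype=np.int8).reshape(1, 1, 3, 3, 3)
    out = infer_int8_activations(qnet, x)["id"]
    np.testing.assert_array_equal(out, x)


def test_int8_inference_is_deterministic_and_bounded(rng):
    qnet, x = make_tiny_qnet(rng)
    a = infer_int8_activations(qnet, x)
    b = infer_int8_activations(qnet, x)
    last = qnet.layers[-1].name
    np.testing.assert_array_equal(a[last], b[last])
    assert a[last].dtype == np.int8


def test_infer_int8_rejects_mismatched_scheme(rng):
    qnet, x = make_tiny_qnet(rng)
    v = Volume(data=x, value_kind="int8-code",
               shift_bits=qnet.input_scheme.shift_bits + 1)
    with pytest.raises(ShapeError, match="scheme"):
        infer_int8(qnet, v)


def test_all_zero_input_gives_constant_labels():
    net, rec, qnet, _ = _toy_quantized(seed=6)
    z = Volume(data=np.zeros((1, 4, 16, 16, 16), dtype=np.int8),
               value_kind="int8-code",
               shift_bits=qnet.input_scheme.shift_bits)
    out = infer_int8(qnet, z)
    from unetq import argmax_labels
    lab = argmax_labels(out).data
    assert np.unique(lab).size == 1


def test_scheme_manifest_roundtrips_through_archive(tmp_path):
    from unetq import load_quantized, save_quantized
    _, _, qnet, _ = _toy_quantized(seed=7)
    p = tmp_path / "q.npz"
    save_quantized(qnet, p)
    back = load_quantized(p)
    assert back.scheme_manifest() == qnet.scheme_manifest()
    for a, b in zip(qnet.layers, back.layers):
        if hasattr(a, "weights"):
            np.testing.assert_array_equal(a.weights, b.weights)
            np.testing.assert_array_equal(a.bias, b.bias)


def test_rescale_codes_inverse_shifts():
    v = np.array([37, -88, 5], dtype=np.int64)
    up = rescale_codes(v, 2, 4, clamp=False)
    np.testing.assert_array_equal(up, v * 4)
    down = rescale_codes(np.array([6, -6, 5]), 4, 2, clamp=False)
    np.testing.assert_array_equal(down, [2, -2, 1])  # 1.25 -> 1, 1.5 -> 2
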