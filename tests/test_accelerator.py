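"""Accelerator model: PE modes, partitioning, instructions, scheduling,
zero-skip and end-to-end semantics preservation."""

import math

import numpy as np
import pytest

from unetq import PartitionError
from unetq.accelerator import (PE_MODES, ComputationBlock, ConvGeometry,
                               Instruction, ResourceConfig,
                               allocate_addresses, decode_instructions,
                               encode_instructions, generate_instructions,
                               partition_layer, run_accelerated, schedule,
                               select_pe_mode, utilization_report, zero_skip)
from unetq.quantize import (calibrate, infer_int8, quantize_network,
                            quantize_volume)
from unetq.folding import fold_network
from unetq.synthetic import PhantomSpec, make_phantom, make_random_network

from ._oracles import schedule_events


def _toy_qnet(seed=1):
    net = fold_network(make_random_network(2, 2, seed=seed))
    vol, _ = make_phantom(PhantomSpec(seed=seed))
    rec = calibrate(net, [vol])
    qnet = quantize_network(net, rec)
    return qnet, quantize_volume(vol, qnet)


# ---------------------------------------------------------------------------
# PE modes


@pytest.mark.parametrize("in_ch,out_ch,name,pixels", [
    (4, 32, "4-32", 4),    # first layer: few input channels
    (32, 32, "32-32", 2),
    (32, 64, "32-64", 1),
    (3, 16, "4-32", 4),    # padded up to the 4-input mode
    (8, 8, "32-32", 2),
])
def test_pe_mode_selection(in_ch, out_ch, name, pixels):
    mode = select_pe_mode(in_ch, out_ch)
    assert mode.name == name
    assert mode.pixels_per_issue == pixels


# ---------------------------------------------------------------------------
# partitioning


def _geom(out_ch=4, in_ch=4, spatial=(8, 8, 8), kernel=(3, 3, 3),
          stride=(1, 1, 1)):
    in_sp = tuple((n - 1) * s + k for n, s, k in zip(spatial, stride, kernel))
    return ConvGeometry(name="L", in_channels=in_ch, out_channels=out_ch,
                        kernel=kernel, stride=stride, in_spatial=in_sp,
                        out_spatial=spatial)


def test_small_layer_fits_in_one_block():
    blocks = partition_layer(_geom(), ResourceConfig())
    assert len(blocks) == 1
    b = blocks[0]
    assert b.channels == (0, 4)
    assert b.out_box == ((0, 8), (0, 8), (0, 8))


def test_blocks_tile_output_exactly_when_capacity_halved():
    g = _geom()
    one = partition_layer(g, ResourceConfig())[0]
    rc = ResourceConfig(output_mem=one.output_bytes)  # half available -> >=2
    blocks = partition_layer(g, rc)
    assert len(blocks) >= 2
    cover = np.zeros((4, 8, 8, 8), dtype=int)
    for b in blocks:
        (c0, c1), ((z0, z1), (y0, y1), (x0, x1)) = b.channels, b.out_box
        cover[c0:c1, z0:z1, y0:y1, x0:x1] += 1
        assert b.output_bytes <= rc.output_mem // 2
        assert b.input_bytes <= rc.input_mem // 2
        assert b.param_bytes <= rc.param_mem // 2
    assert (cover == 1).all()  # exact tiling, no overlap


def test_shrinking_capacity_never_decreases_block_count():
    g = _geom(out_ch=8, spatial=(8, 8, 8))
    for field in ("input_mem", "param_mem", "output_mem"):
        counts = []
        for cap in (1 << 16, 1 << 14, 1 << 12, 1 << 10, 1 << 9):
            rc = ResourceConfig(**{field: cap})
            counts.append(len(partition_layer(g, rc)))
        assert counts == sorted(counts)


def test_infeasible_partition_names_layer():
    g = _geom(in_ch=16)
    with pytest.raises(PartitionError, match="L"):
        partition_layer(g, ResourceConfig(input_mem=64))


# ---------------------------------------------------------------------------
# addresses and instructions


def test_ping_pong_addresses_are_disjoint():
    g = _geom()
    rc = ResourceConfig(output_mem=512, input_mem=4096, param_mem=2048)
    blocks = partition_layer(g, rc)
    addrs = allocate_addresses(blocks, rc)
    assert len(blocks) >= 2
    for a, b_addr, blk_a, blk_b in zip(addrs, addrs[1:], blocks, blocks[1:]):
        # consecutive (potentially concurrent) blocks: disjoint intervals
        for mem, size_a, size_b in (
            ("input", blk_a.input_bytes, blk_b.input_bytes),
            ("output", blk_a.output_bytes, blk_b.output_bytes),
            ("weights", blk_a.param_bytes, blk_b.param_bytes),
        ):
            a0, a1 = getattr(a, mem), getattr(a, mem) + size_a
            b0, b1 = getattr(b_addr, mem), getattr(b_addr, mem) + size_b
            assert a1 <= b0 or b1 <= a0


def test_single_block_sits_at_offset_zero():
    blocks = partition_layer(_geom(), ResourceConfig())
    addr = allocate_addresses(blocks, ResourceConfig())[0]
    assert addr.input == addr.weights == addr.output == 0


def test_ex_cycles_are_ceiling_of_padded_macs_over_lanes():
    rc = ResourceConfig(load_bandwidth=16, writeback_bandwidth=16)
    # a 4-32-mode block: 4 in, 32 out channels, 1x1x1 kernel, 16 pixels
    b = ComputationBlock(layer="L", pe_mode="4-32", channels=(0, 32),
                         out_box=((0, 1), (0, 4), (0, 4)),
                         in_box=((0, 1), (0, 4), (0, 4)), in_channels=4,
                         kernel=(1, 1, 1))
    [ins] = generate_instructions([b], rc)
    lanes = PE_MODES["4-32"].lanes  # 4*32*4 = 512
    assert ins.ex == math.ceil(4 * 32 * 16 / lanes) == 4
    assert ins.ld == math.ceil((b.input_bytes + b.param_bytes) / 16)
    assert ins.wb == math.ceil(b.output_bytes / 16)
    assert ins.cf == rc.cycles_per_config


def test_zero_pixel_free_block_has_zero_ex():
    b = ComputationBlock(layer="L", pe_mode="4-32", channels=(0, 0),
                         out_box=((0, 1), (0, 1), (0, 1)),
                         in_box=((0, 1), (0, 1), (0, 1)), in_channels=0,
                         kernel=(1, 1, 1))
    [ins] = generate_instructions([b], ResourceConfig())
    assert ins.ex == 0


def test_instruction_binary_roundtrip():
    qnet, qv = _toy_qnet()
    res = run_accelerated(qnet, qv, ResourceConfig(input_mem=2048,
                                                   output_mem=2048))
    blob = encode_instructions(res.instructions)
    back = decode_instructions(blob)
    assert len(back) == len(res.instructions)
    for a, b in zip(res.instructions, back):
        assert (a.opcode, a.mode, a.layer_id, a.cf, a.ld, a.ex, a.wb,
                a.input_addr, a.weight_addr, a.bias_addr, a.output_addr) == \
               (b.opcode, b.mode, b.layer_id, b.cf, b.ld, b.ex, b.wb,
                b.input_addr, b.weight_addr, b.bias_addr, b.output_addr)


# ---------------------------------------------------------------------------
# scheduling


def _instr(i, layer, cf, ld, ex, wb):
    return Instruction(index=i, layer_id=layer, opcode=1, mode="32-32",
                       cf=cf, ld=ld, ex=ex, wb=wb)


def test_single_instruction_same_makespan_both_modes():
    ins = [_instr(0, 0, 3, 5, 7, 2)]
    assert schedule(ins, True).makespan == 17
    assert schedule(ins, False).makespan == 17


def test_dominant_ex_masks_other_stages():
    """Uniform costs with e >= c+l+w: makespan = c + l + N*e + w."""
    c, l, e, w, n = 2, 3, 9, 1, 7
    ins = [_instr(i, 0, c, l, e, w) for i in range(n)]
    tr = schedule(ins, True)
    tr.validate()
    assert tr.makespan == c + l + n * e + w
    assert schedule(ins, False).makespan == n * (c + l + e + w)


@pytest.mark.parametrize("seed", range(8))
def test_random_programs_match_event_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 20))
    layers = np.sort(rng.integers(0, 4, size=n))
    costs = [(int(layers[i]), *map(int, rng.integers(0, 12, size=4)))
             for i in range(n)]
    ins = [_instr(i, c[0], *c[1:]) for i, c in enumerate(costs)]
    for db in (True, False):
        tr = schedule(ins, db)
        tr.validate()
        want = schedule_events(costs, db)
        for e in tr.entries:
            for stage in ("cf", "ld", "ex", "wb"):
                assert getattr(e, stage) == want[e.index][stage], \
                    f"instr {e.index} stage {stage} (db={db})"
        assert tr.makespan <= schedule(ins, False).makespan


def test_double_buffering_never_slower(rng):
    for _ in range(30):
        n = int(rng.integers(1, 15))
        ins = [_instr(i, 0, *map(int, rng.integers(0, 10, size=4)))
               for i in range(n)]
        assert schedule(ins, True).makespan <= schedule(ins, False).makespan


# ---------------------------------------------------------------------------
# zero-skip


def test_zero_skip_splits_on_region_content(rng):
    g = _geom(out_ch=2, in_ch=1, spatial=(4, 4, 4), kernel=(1, 1, 1))
    rc = ResourceConfig(output_mem=16)
    blocks = partition_layer(g, rc)
    x = np.zeros((1, 1, 4, 4, 4), dtype=np.int8)
    kept, skipped = zero_skip(blocks, x)
    assert not kept and len(skipped) == len(blocks)
    x[...] = 1
    kept, skipped = zero_skip(blocks, x)
    assert not skipped and len(kept) == len(blocks)


def test_skipped_schedule_is_bit_identical_and_skips_blocks():
    """On a 70%-zero phantom, skipping changes nothing but the schedule."""
    qnet, qv = _toy_qnet(seed=3)
    rc = ResourceConfig(input_mem=512, output_mem=512, param_mem=8192)
    skipped = run_accelerated(qnet, qv, rc, skip_zero_blocks=True)
    full = run_accelerated(qnet, qv, rc, skip_zero_blocks=False)
    np.testing.assert_array_equal(skipped.scores.data, full.scores.data)
    assert skipped.skipped_blocks > 0
    assert skipped.report["skipped_block_fraction"] > 0
    assert full.skipped_blocks == 0
    assert skipped.trace.makespan < full.trace.makespan


# ---------------------------------------------------------------------------
# semantics preservation + utilization


@pytest.mark.parametrize("seed", [2, 5])
def test_any_partition_reproduces_reference_inference(seed):
    qnet, qv = _toy_qnet(seed=seed)
    want = infer_int8(qnet, qv).data
    rng = np.random.default_rng(seed)
    for _ in range(4):
        rc = ResourceConfig(
            input_mem=int(rng.integers(600, 8192)),
            param_mem=int(rng.integers(1024, 32768)),
            output_mem=int(rng.integers(128, 4096)),
            load_bandwidth=int(rng.integers(8, 128)),
            writeback_bandwidth=int(rng.integers(8, 128)))
        for skip in (True, False):
            res = run_accelerated(qnet, qv, rc, skip_zero_blocks=skip)
            np.testing.assert_array_equal(res.scores.data, want)
            res.trace.validate()


def test_full_pe_block_reaches_unit_occupancy():
    rc = ResourceConfig()
    b = ComputationBlock(layer="L", pe_mode="32-64", channels=(0, 64),
                         out_box=((0, 2), (0, 2), (0, 2)),
                         in_box=((0, 2), (0, 2), (0, 2)), in_channels=32,
                         kernel=(1, 1, 1))
    ins = generate_instructions([b], rc)
    rep = utilization_report(schedule(ins), rc)
    assert rep["mode_occupancy"]["32-64"]["occupancy"] == pytest.approx(1.0)


def test_three_channel_input_occupies_three_quarter_lanes():
    rc = ResourceConfig()
    b = ComputationBlock(layer="L", pe_mode="4-32", channels=(0, 32),
                         out_box=((0, 2), (0, 2), (0, 2)),
                         in_box=((0, 2), (0, 2), (0, 2)), in_channels=3,
                         kernel=(1, 1, 1))
    ins = generate_instructions([b], rc)
    rep = utilization_report(schedule(ins), rc)
    assert rep["mode_occupancy"]["4-32"]["occupancy"] == pytest.approx(0.75)


def test_double_buffering_raises_ex_busy_fraction():
    qnet, qv = _toy_qnet(seed=4)
    rc = ResourceConfig(input_mem=1024, output_mem=1024)
    db = run_accelerated(qnet, qv, rc, double_buffered=True)
    ser = run_accelerated(qnet, qv, rc, double_buffered=False)
    assert db.report["stage_busy_fraction"]["ex"] >= \
        ser.report["stage_busy_fraction"]["ex"]
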