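"""Behavioral and cycle-approximate model of the FPGA accelerator.

The accelerator executes a quantized network layer by layer: each layer is
partitioned into computation blocks that fit on-chip memory, one instruction
is generated per block, and instructions run through four stages —
configuration (CF), load (LD), execute (EX), write-back (WB).  Stage
durations differ per instruction, so instead of a classic fixed-slot
pipeline a double-buffering (ping-pong) scheme overlaps consecutive
instructions: at most two are in flight, each stage resource serves one
instruction at a time, and the longest stage hides the others.

The processing-element array has three fixed modes — 4-32, 32-32 and 32-64
(input channels - output channels), computing 4 / 2 / 1 feature-map pixels
per issue respectively.  Layers whose channel counts do not match a mode are
zero-padded to the nearest mode; padded lanes count as idle in the
utilization report.

Stage costs are linear in bytes moved / MACs executed with configurable
coefficients (the ResourceConfig): the model is parametric and validated by
its invariants (semantics preservation, double-buffered makespan never worse
than serial, bit-exact zero-skipping), not by absolute cycle counts.

Zero-block skipping: a computation block whose entire required input region
is zero — common downstream of the zero-insertion in deconvolution layers
and in the empty exterior of brain volumes — is dropped from the instruction
stream and its output is filled with the bias-only value, which is exactly
what convolving a zero region produces.  The skipped schedule is therefore
bit-identical to the full one.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from . import decompose, ops
from .errors import PartitionError, ShapeError, UnetqError
from .layers import Triple, Volume
from .network import argmax_labels
from .quantize import (INT32_MAX, AccumulatorOverflow, QuantizedLayer,
                       QuantizedNetwork, aligned_bias, effective_conv,
                       rescale_codes)

# ---------------------------------------------------------------------------
# PE modes


@dataclass(frozen=True)
class PEMode:
    name: str
    in_ch: int
    out_ch: int
    pixels_per_issue: int

    @property
    def lanes(self) -> int:
        """Multipliers active per issue cycle."""
        return self.in_ch * self.out_ch * self.pixels_per_issue


PE_MODES = {
    "4-32": PEMode("4-32", 4, 32, 4),
    "32-32": PEMode("32-32", 32, 32, 2),
    "32-64": PEMode("32-64", 32, 64, 1),
}

_MODE_IDS = {name: i for i, name in enumerate(PE_MODES)}


def select_pe_mode(in_channels: int, out_channels: int) -> PEMode:
    """Pick the PE mode for a layer; off-grid channel counts are padded to
    the nearest mode (first layers with few channels use 4-32)."""
    if in_channels <= 4:
        return PE_MODES["4-32"]
    if out_channels <= 32:
        return PE_MODES["32-32"]
    return PE_MODES["32-64"]


# ---------------------------------------------------------------------------
# resource configuration


@dataclass
class ResourceConfig:
    """On-chip capacities and cost coefficients of the cycle model.

    Memory capacities are bytes (int8 codes are one byte); each of the three
    data memories is split into two ping-pong halves for double-buffering,
    so a single computation block may use at most half of each capacity.
    Bandwidths are bytes per cycle; ``cycles_per_config`` is the fixed CF
    stage cost per instruction.
    """

    input_mem: int = 262144
    param_mem: int = 262144
    output_mem: int = 262144
    pe_multipliers: int = 2048
    load_bandwidth: int = 64
    writeback_bandwidth: int = 64
    cycles_per_config: int = 8

    def __post_init__(self) -> None:
        for name in ("input_mem", "param_mem", "output_mem", "pe_multipliers",
                     "load_bandwidth", "writeback_bandwidth",
                     "cycles_per_config"):
            if getattr(self, name) <= 0:
                raise UnetqError(f"ResourceConfig.{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "ResourceConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)


# ---------------------------------------------------------------------------
# layer geometry and computation blocks


@dataclass(frozen=True)
class ConvGeometry:
    """The ordinary convolution a layer reduces to, in padded coordinates.

    For deconvolution layers the input spatial size is that of the
    zero-inserted, fully padded input and the stride is 1; partitioning and
    zero detection operate on this effective convolution.
    """

    name: str
    in_channels: int
    out_channels: int
    kernel: Triple
    stride: Triple
    in_spatial: Triple  # padded effective input
    out_spatial: Triple

    @classmethod
    def from_qlayer(cls, ql: QuantizedLayer, input_spatial: Triple
                    ) -> "ConvGeometry":
        if ql.transposed:
            eff = tuple((n - 1) * s + 1 + 2 * (k - 1 - p) for n, s, k, p in
                        zip(input_spatial, ql.stride, ql.kernel, ql.padding))
            stride = (1, 1, 1)
        else:
            eff = tuple(n + 2 * p for n, p in zip(input_spatial, ql.padding))
            stride = ql.stride
        out = tuple((n - k) // s + 1 for n, k, s in zip(eff, ql.kernel, stride))
        if any(o < 1 for o in out):
            raise ShapeError(f"layer {ql.name!r}: input too small")
        return cls(name=ql.name, in_channels=ql.in_channels,
                   out_channels=ql.out_channels, kernel=ql.kernel,
                   stride=stride, in_spatial=eff, out_spatial=out)


@dataclass
class ComputationBlock:
    """One tile of a layer's output and the input region it requires."""

    layer: str
    pe_mode: str
    channels: tuple[int, int]  # [c0, c1) of the output channel axis
    out_box: tuple[tuple[int, int], ...]  # [(z0,z1),(y0,y1),(x0,x1)]
    in_box: tuple[tuple[int, int], ...]  # padded effective input coords
    in_channels: int
    kernel: Triple
    zero_input: bool = False

    @property
    def out_channel_count(self) -> int:
        return self.channels[1] - self.channels[0]

    @property
    def n_pixels(self) -> int:
        return math.prod(b - a for a, b in self.out_box)

    @property
    def input_bytes(self) -> int:
        return self.in_channels * math.prod(b - a for a, b in self.in_box)

    @property
    def weight_bytes(self) -> int:
        return self.out_channel_count * self.in_channels * math.prod(self.kernel)

    @property
    def param_bytes(self) -> int:
        return self.weight_bytes + self.out_channel_count  # + int8 biases

    @property
    def output_bytes(self) -> int:
        return self.out_channel_count * self.n_pixels

    @property
    def macs(self) -> int:
        return (self.in_channels * self.out_channel_count
                * math.prod(self.kernel) * self.n_pixels)


def _ranges(total: int, step: int) -> list[tuple[int, int]]:
    return [(i, min(i + step, total)) for i in range(0, total, step)]


def partition_layer(geom: ConvGeometry, rc: ResourceConfig
                    ) -> list[ComputationBlock]:
    """Tile a layer's output into blocks that fit the on-chip memories.

    Deterministic greedy refinement: the output channel group is halved
    until the block's parameters fit the parameter memory; then the largest
    spatial extent is halved (depth before height before width on ties)
    until the input region and output tile fit their memories.  Blocks are
    emitted output-channel-group-major, then z, y, x ascending, and tile the
    output exactly with no overlap.
    """
    mode = select_pe_mode(geom.in_channels, geom.out_channels)
    param_cap = rc.param_mem // 2
    in_cap = rc.input_mem // 2
    out_cap = rc.output_mem // 2
    kvol = math.prod(geom.kernel)

    c = geom.out_channels
    while c * (geom.in_channels * kvol + 1) > param_cap:
        if c == 1:
            raise PartitionError(
                f"layer {geom.name!r}: parameters of a single output channel "
                f"exceed the parameter memory"
            )
        c = (c + 1) // 2

    dims = list(geom.out_spatial)

    def in_bytes(d) -> int:
        return geom.in_channels * math.prod(
            (n - 1) * s + k for n, s, k in zip(d, geom.stride, geom.kernel))

    def out_bytes(d) -> int:
        return c * math.prod(d)

    while in_bytes(dims) > in_cap or out_bytes(dims) > out_cap:
        if max(dims) > 1:
            dims[dims.index(max(dims))] = (max(dims) + 1) // 2
        elif c > 1 and out_bytes(dims) > out_cap:
            c = (c + 1) // 2
        else:
            raise PartitionError(
                f"layer {geom.name!r}: a minimal computation block exceeds "
                f"on-chip capacity"
            )

    blocks = []
    for c0, c1 in _ranges(geom.out_channels, c):
        for z0, z1 in _ranges(geom.out_spatial[0], dims[0]):
            for y0, y1 in _ranges(geom.out_spatial[1], dims[1]):
                for x0, x1 in _ranges(geom.out_spatial[2], dims[2]):
                    out_box = ((z0, z1), (y0, y1), (x0, x1))
                    in_box = tuple(
                        (a * s, (b - 1) * s + k)
                        for (a, b), s, k in zip(out_box, geom.stride,
                                                geom.kernel))
                    blocks.append(ComputationBlock(
                        layer=geom.name, pe_mode=mode.name,
                        channels=(c0, c1), out_box=out_box, in_box=in_box,
                        in_channels=geom.in_channels, kernel=geom.kernel))
    return blocks


# ---------------------------------------------------------------------------
# addresses


@dataclass(frozen=True)
class BlockAddresses:
    input: int
    weights: int
    bias: int
    output: int


def allocate_addresses(blocks: list[ComputationBlock], rc: ResourceConfig
                       ) -> list[BlockAddresses]:
    """Ping-pong address allocation: consecutive blocks alternate between
    the two disjoint halves of each data memory."""
    out = []
    for i, b in enumerate(blocks):
        parity = i % 2
        addr = BlockAddresses(
            input=parity * (rc.input_mem // 2),
            weights=parity * (rc.param_mem // 2),
            bias=parity * (rc.param_mem // 2) + b.weight_bytes,
            output=parity * (rc.output_mem // 2),
        )
        for a, nbytes, cap in (
            (addr.input, b.input_bytes, rc.input_mem),
            (addr.weights, b.param_bytes, rc.param_mem),
            (addr.output, b.output_bytes, rc.output_mem),
        ):
            half = cap // 2
            if half == 0 or (a % half) + nbytes > half:
                raise PartitionError(
                    f"block of layer {b.layer!r} overflows its buffer half"
                )
        out.append(addr)
    return out


# ---------------------------------------------------------------------------
# instructions


OPCODE_CONV = 1
OPCODE_DECONV = 2

_INSTR_STRUCT = struct.Struct("<BBHIIIIIIIIQQ")
_HEADER_STRUCT = struct.Struct("<4sHI")
_MAGIC = b"UQIS"


@dataclass
class Instruction:
    index: int
    layer_id: int
    opcode: int
    mode: str
    cf: int
    ld: int
    ex: int
    wb: int
    input_addr: int = 0
    weight_addr: int = 0
    bias_addr: int = 0
    output_addr: int = 0
    macs_true: int = 0
    macs_padded: int = 0

    @property
    def total(self) -> int:
        return self.cf + self.ld + self.ex + self.wb


def _padded_macs(b: ComputationBlock, mode: PEMode) -> int:
    def up(n, m):
        return ((n + m - 1) // m) * m

    return (up(b.in_channels, mode.in_ch)
            * up(b.out_channel_count, mode.out_ch)
            * up(b.n_pixels, mode.pixels_per_issue)
            * math.prod(b.kernel))


def generate_instructions(blocks: list[ComputationBlock], rc: ResourceConfig,
                          addresses: list[BlockAddresses] | None = None,
                          layer_id: int = 0, opcode: int = OPCODE_CONV,
                          start_index: int = 0) -> list[Instruction]:
    """One instruction per block with the four stage costs.

    EX = ceil(MACs / active multipliers per cycle), counted on the
    channel/pixel-padded MAC count (padded lanes run but do no useful work);
    LD and WB are ceil(bytes / bandwidth); CF is the fixed configuration
    cost.
    """
    if addresses is None:
        addresses = allocate_addresses(blocks, rc)
    instrs = []
    for i, (b, addr) in enumerate(zip(blocks, addresses)):
        mode = PE_MODES[b.pe_mode]
        padded = _padded_macs(b, mode)
        instrs.append(Instruction(
            index=start_index + i, layer_id=layer_id, opcode=opcode,
            mode=b.pe_mode,
            cf=rc.cycles_per_config,
            ld=-(-(b.input_bytes + b.param_bytes) // rc.load_bandwidth),
            ex=-(-padded // mode.lanes) if b.macs else 0,
            wb=-(-b.output_bytes // rc.writeback_bandwidth),
            input_addr=addr.input, weight_addr=addr.weights,
            bias_addr=addr.bias, output_addr=addr.output,
            macs_true=b.macs, macs_padded=padded,
        ))
    return instrs


def encode_instructions(instrs: list[Instruction]) -> bytes:
    """Serialize to the documented binary format (little-endian, versioned)."""
    out = [_HEADER_STRUCT.pack(_MAGIC, 1, len(instrs))]
    for ins in instrs:
        out.append(_INSTR_STRUCT.pack(
            ins.opcode, _MODE_IDS[ins.mode], ins.layer_id,
            ins.cf, ins.ld, ins.ex, ins.wb,
            ins.input_addr, ins.weight_addr, ins.bias_addr, ins.output_addr,
            ins.macs_true, ins.macs_padded))
    return b"".join(out)


def decode_instructions(blob: bytes) -> list[Instruction]:
    if len(blob) < _HEADER_STRUCT.size:
        raise UnetqError("instruction stream too short")
    magic, version, count = _HEADER_STRUCT.unpack_from(blob)
    if magic != _MAGIC or version != 1:
        raise UnetqError("not a recognized instruction stream")
    names = list(PE_MODES)
    instrs = []
    off = _HEADER_STRUCT.size
    for i in range(count):
        (opcode, mode_id, layer_id, cf, ld, ex, wb, ia, wa, ba, oa,
         mt, mp) = _INSTR_STRUCT.unpack_from(blob, off)
        off += _INSTR_STRUCT.size
        instrs.append(Instruction(
            index=i, layer_id=layer_id, opcode=opcode, mode=names[mode_id],
            cf=cf, ld=ld, ex=ex, wb=wb, input_addr=ia, weight_addr=wa,
            bias_addr=ba, output_addr=oa, macs_true=mt, macs_padded=mp))
    return instrs


# ---------------------------------------------------------------------------
# zero-block skipping


def zero_skip(blocks: list[ComputationBlock], x_eff: np.ndarray
              ) -> tuple[list[ComputationBlock], list[ComputationBlock]]:
    """Split blocks into (kept, skipped) by testing each block's input region.

    ``x_eff`` is the padded effective input, shaped (b, c, D, H, W) or
    (c, D, H, W).  A block is skipped iff every code in its required input
    region is zero; its output is then the bias-only value, so dropping it
    cannot change the result.
    """
    if x_eff.ndim == 4:
        x_eff = x_eff[None]
    kept, skipped = [], []
    for b in blocks:
        (z0, z1), (y0, y1), (x0, x1) = b.in_box
        region = x_eff[:, :, z0:z1, y0:y1, x0:x1]
        if region.any():
            kept.append(b)
        else:
            skipped.append(replace(b, zero_input=True))
    return kept, skipped


# ---------------------------------------------------------------------------
# scheduling


@dataclass
class StageTiming:
    index: int
    layer_id: int
    mode: str
    cf: tuple[int, int]
    ld: tuple[int, int]
    ex: tuple[int, int]
    wb: tuple[int, int]
    macs_true: int = 0
    macs_padded: int = 0

    @property
    def start(self) -> int:
        return self.cf[0]

    @property
    def end(self) -> int:
        return self.wb[1]


@dataclass
class ScheduleTrace:
    entries: list[StageTiming]
    double_buffered: bool

    @property
    def makespan(self) -> int:
        return max((e.end for e in self.entries), default=0)

    def busy(self) -> dict[str, int]:
        out = {}
        for stage in ("cf", "ld", "ex", "wb"):
            out[stage] = sum(
                getattr(e, stage)[1] - getattr(e, stage)[0]
                for e in self.entries)
        return out

    def validate(self) -> None:
        """Check the structural invariants of a valid trace."""
        for e in self.entries:
            seq = [*e.cf, *e.ld, *e.ex, *e.wb]
            if any(b < a for a, b in zip(seq, seq[1:])):
                raise UnetqError(f"instruction {e.index}: stages out of order")
        for stage in ("cf", "ld", "ex", "wb"):
            iv = sorted(getattr(e, stage) for e in self.entries)
            for (a0, a1), (b0, b1) in zip(iv, iv[1:]):
                if b0 < a1:
                    raise UnetqError(f"{stage} resource double-booked")
        for i in range(2, len(self.entries)):
            if self.entries[i].start < self.entries[i - 2].end:
                raise UnetqError("more than two instructions in flight")
        # layer-by-layer: EX of layer k+1 waits for all layer-k write-backs
        max_wb: dict[int, int] = {}
        for e in self.entries:
            max_wb[e.layer_id] = max(max_wb.get(e.layer_id, 0), e.wb[1])
        for e in self.entries:
            barrier = max((t for lid, t in max_wb.items()
                           if lid < e.layer_id), default=0)
            if e.ex[0] < barrier:
                raise UnetqError("EX started before previous layer completed")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append({"instr": e.index, "layer_id": e.layer_id,
                         "mode": e.mode,
                         "cf_start": e.cf[0], "cf_end": e.cf[1],
                         "ld_start": e.ld[0], "ld_end": e.ld[1],
                         "ex_start": e.ex[0], "ex_end": e.ex[1],
                         "wb_start": e.wb[0], "wb_end": e.wb[1]})
        return pd.DataFrame(rows)


def schedule(instrs: list[Instruction], double_buffered: bool = True
             ) -> ScheduleTrace:
    """Timeline of the instruction stream.

    Without double-buffering instructions run strictly one after another, so
    the makespan is the sum of all stage costs.  With it, a stage resource
    serves one instruction at a time, stages of one instruction stay in
    order, at most two instructions are in flight, and the EX stage of a new
    layer waits for every write-back of the previous layer (load prefetch
    may overlap the boundary).
    """
    entries: list[StageTiming] = []
    cf_free = ld_free = ex_free = wb_free = 0
    finish: list[int] = []
    barrier = 0
    max_wb_seen = 0
    cur_layer: int | None = None
    for ins in instrs:
        if cur_layer is not None and ins.layer_id != cur_layer:
            barrier = max_wb_seen
        cur_layer = ins.layer_id
        if double_buffered:
            cf_s = max(cf_free, finish[-2] if len(finish) >= 2 else 0)
        else:
            cf_s = finish[-1] if finish else 0
        cf_e = cf_s + ins.cf
        ld_s = max(cf_e, ld_free)
        ld_e = ld_s + ins.ld
        ex_s = max(ld_e, ex_free, barrier)
        ex_e = ex_s + ins.ex
        wb_s = max(ex_e, wb_free)
        wb_e = wb_s + ins.wb
        cf_free, ld_free, ex_free, wb_free = cf_e, ld_e, ex_e, wb_e
        finish.append(wb_e)
        max_wb_seen = max(max_wb_seen, wb_e)
        entries.append(StageTiming(
            index=ins.index, layer_id=ins.layer_id, mode=ins.mode,
            cf=(cf_s, cf_e), ld=(ld_s, ld_e), ex=(ex_s, ex_e),
            wb=(wb_s, wb_e), macs_true=ins.macs_true,
            macs_padded=ins.macs_padded))
    return ScheduleTrace(entries=entries, double_buffered=double_buffered)


def utilization_report(trace: ScheduleTrace, rc: ResourceConfig) -> dict:
    """Multiplier occupancy per PE mode and stage-overlap statistics.

    Occupancy is useful multiplier-cycles over issued multiplier-cycles
    (mode lane count times EX-busy cycles); zero-padded channel and pixel
    lanes are idle, so layers that do not fill a mode score below 1.
    """
    makespan = trace.makespan
    busy = trace.busy()
    per_mode = {}
    for name, mode in PE_MODES.items():
        es = [e for e in trace.entries if e.mode == name]
        ex_cycles = sum(e.ex[1] - e.ex[0] for e in es)
        issued = mode.lanes * ex_cycles
        per_mode[name] = {
            "instructions": len(es),
            "ex_cycles": ex_cycles,
            "occupancy": (sum(e.macs_true for e in es) / issued
                          if issued else None),
        }
    return {
        "makespan": makespan,
        "double_buffered": trace.double_buffered,
        "stage_busy_cycles": busy,
        "stage_busy_fraction": {
            k: (v / makespan if makespan else 0.0) for k, v in busy.items()},
        "mode_occupancy": per_mode,
    }


# ---------------------------------------------------------------------------
# full-network execution


@dataclass
class SimResult:
    scores: Volume  # classifier output codes
    labels: Volume
    instructions: list[Instruction]
    trace: ScheduleTrace
    report: dict
    total_blocks: int
    skipped_blocks: int

    @property
    def skipped_fraction(self) -> float:
        return self.skipped_blocks / self.total_blocks if self.total_blocks else 0.0


def run_accelerated(qnet: QuantizedNetwork, v: Volume, rc: ResourceConfig,
                    double_buffered: bool = True,
                    skip_zero_blocks: bool = True) -> SimResult:
    """Execute a quantized network block by block under the resource model.

    The block outputs are computed with the same integer arithmetic as
    ``infer_int8``, so any valid partition reproduces its result bit-exactly;
    partitioning and skipping change the schedule, never the values.
    """
    if v.value_kind != "int8-code" or v.shift_bits != qnet.input_scheme.shift_bits:
        raise ShapeError("run_accelerated needs an int8-code volume on the "
                         "network input scheme (use quantize_volume)")
    acts: dict[str, np.ndarray] = {"input": np.asarray(v.data, dtype=np.int8)}
    scheme_of = {"input": qnet.input_scheme}
    instrs: list[Instruction] = []
    total_blocks = skipped_blocks = 0
    layer_id = 0
    for lay in qnet.layers:
        xs = [acts[s] for s in lay.inputs]
        if isinstance(lay, QuantizedLayer):
            x = rescale_codes(xs[0], scheme_of[lay.inputs[0]].shift_bits,
                              lay.input_scheme.shift_bits).astype(np.int8)
            acts[lay.name] = _run_conv_blocks(
                lay, x, rc, layer_id, instrs, skip_zero_blocks,
                counters := [0, 0])
            total_blocks += counters[0]
            skipped_blocks += counters[1]
            layer_id += 1
        elif lay.op == "relu":
            acts[lay.name] = np.maximum(xs[0], 0)
        elif lay.op == "maxpool":
            acts[lay.name] = ops.maxpool2(xs[0])
        elif lay.op == "concat":
            t = lay.output_scheme.shift_bits
            acts[lay.name] = np.concatenate(
                [rescale_codes(xi, scheme_of[s].shift_bits, t).astype(np.int8)
                 for xi, s in zip(xs, lay.inputs)], axis=1)
        scheme_of[lay.name] = lay.output_scheme
    trace = schedule(instrs, double_buffered=double_buffered)
    report = utilization_report(trace, rc)
    report["total_blocks"] = total_blocks
    report["skipped_blocks"] = skipped_blocks
    report["skipped_block_fraction"] = (
        skipped_blocks / total_blocks if total_blocks else 0.0)
    last = qnet.layers[-1]
    scores = Volume(data=acts[last.name], value_kind="int8-code",
                    shift_bits=last.output_scheme.shift_bits, affine=v.affine)
    return SimResult(scores=scores, labels=argmax_labels(scores),
                     instructions=instrs, trace=trace, report=report,
                     total_blocks=total_blocks, skipped_blocks=skipped_blocks)


def _run_conv_blocks(ql: QuantizedLayer, x: np.ndarray, rc: ResourceConfig,
                     layer_id: int, instrs: list[Instruction],
                     skip_zero_blocks: bool, counters: list[int]
                     ) -> np.ndarray:
    w_eff, stride, pad, pre = effective_conv(ql)
    xe = pre(x.astype(np.int64))
    xpad = ops.pad3d(xe, pad)
    geom = ConvGeometry(
        name=ql.name, in_channels=ql.in_channels,
        out_channels=ql.out_channels, kernel=ql.kernel, stride=stride,
        in_spatial=tuple(xpad.shape[2:5]),
        out_spatial=tuple((n - k) // s + 1 for n, k, s in
                          zip(xpad.shape[2:5], ql.kernel, stride)))
    blocks = partition_layer(geom, rc)
    counters[0] = len(blocks)
    if skip_zero_blocks:
        kept, skipped = zero_skip(blocks, xpad)
    else:
        kept, skipped = blocks, []
    counters[1] = len(skipped)
    opcode = OPCODE_DECONV if ql.transposed else OPCODE_CONV
    instrs.extend(generate_instructions(
        kept, rc, layer_id=layer_id, opcode=opcode, start_index=len(instrs)))

    out = np.empty((x.shape[0], ql.out_channels, *geom.out_spatial),
                   dtype=np.int8)
    bias_acc = aligned_bias(ql)
    bias_code = rescale_codes(bias_acc, ql.acc_shift,
                              ql.output_scheme.shift_bits).astype(np.int8)
    for b in skipped:
        (z0, z1), (y0, y1), (x0, x1) = b.out_box
        c0, c1 = b.channels
        out[:, c0:c1, z0:z1, y0:y1, x0:x1] = \
            bias_code[c0:c1].reshape(1, -1, 1, 1, 1)
    for b in kept:
        (iz0, iz1), (iy0, iy1), (ix0, ix1) = b.in_box
        (z0, z1), (y0, y1), (x0, x1) = b.out_box
        c0, c1 = b.channels
        ks = decompose.decompose_kernel(w_eff[c0:c1])
        acc = decompose.conv3d_via_2d(
            xpad[:, :, iz0:iz1, iy0:iy1, ix0:ix1], ks, stride, (0, 0, 0))
        acc = acc + bias_acc[c0:c1].reshape(1, -1, 1, 1, 1)
        if np.abs(acc).max(initial=0) > INT32_MAX:
            raise AccumulatorOverflow(
                f"layer {ql.name!r}: accumulator exceeds 32-bit signed range")
        out[:, c0:c1, z0:z1, y0:y1, x0:x1] = rescale_codes(
            acc, ql.acc_shift, ql.output_scheme.shift_bits).astype(np.int8)
    return out
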