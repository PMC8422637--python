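"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately written in the most literal style possible
(nested loops, Python integers, event queues) and shares no code with the
library's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def conv3d_loops(x, w, stride=(1, 1, 1), padding=(0, 0, 0)):
    """Direct six-nested-loop 3D cross-correlation (float or int)."""
    B, C, D, H, W = x.shape
    O, C2, kd, kh, kw = w.shape
    assert C == C2
    sd, sh, sw = stride
    pd, ph, pw = padding
    Do = (D + 2 * pd - kd) // sd + 1
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    integer = np.issubdtype(x.dtype, np.integer)
    out = np.zeros((B, O, Do, Ho, Wo), dtype=np.int64 if integer else np.float64)
    for b in range(B):
        for o in range(O):
            for z in range(Do):
                for y in range(Ho):
                    for xx in range(Wo):
                        acc = 0
                        for c in range(C):
                            for dz in range(kd):
                                iz = z * sd + dz - pd
                                if not 0 <= iz < D:
                                    continue
                                for dy in range(kh):
                                    iy = y * sh + dy - ph
                                    if not 0 <= iy < H:
                                        continue
                                    for dx in range(kw):
                                        ix = xx * sw + dx - pw
                                        if not 0 <= ix < W:
                                            continue
                                        acc += w[o, c, dz, dy, dx] * x[b, c, iz, iy, ix]
                        out[b, o, z, y, xx] = acc
    return out


def deconv3d_scatter(x, w, stride=(2, 2, 2), padding=(0, 0, 0)):
    """Transposed convolution by direct scattering of input contributions."""
    B, C, D, H, W = x.shape
    O = w.shape[0]
    kd, kh, kw = w.shape[2:5]
    sd, sh, sw = stride
    pd, ph, pw = padding
    Do = (D - 1) * sd + kd - 2 * pd
    Ho = (H - 1) * sh + kh - 2 * ph
    Wo = (W - 1) * sw + kw - 2 * pw
    integer = np.issubdtype(x.dtype, np.integer)
    out = np.zeros((B, O, Do, Ho, Wo), dtype=np.int64 if integer else np.float64)
    for b in range(B):
        for o in range(O):
            for c in range(C):
                for z in range(D):
                    for y in range(H):
                        for xx in range(W):
                            v = x[b, c, z, y, xx]
                            for dz in range(kd):
                                oz = z * sd + dz - pd
                                if not 0 <= oz < Do:
                                    continue
                                for dy in range(kh):
                                    oy = y * sh + dy - ph
                                    if not 0 <= oy < Ho:
                                        continue
                                    for dx in range(kw):
                                        ox = xx * sw + dx - pw
                                        if not 0 <= ox < Wo:
                                            continue
                                        out[b, o, oz, oy, ox] += v * w[o, c, dz, dy, dx]
    return out


# ---------------------------------------------------------------------------
# unbounded-precision int8 inference


def _rshift_round_int(v: int, s: int) -> int:
    """Arithmetic right shift with round-half-away-from-zero, on a Python int."""
    if s == 0:
        return v
    m = 1 << (s - 1)
    if v >= 0:
        return (v + m) >> s
    return -((-v + m) >> s)


def _rescale_int(v: int, frm: int, to: int, clamp: bool = True) -> int:
    d = to - frm
    out = v << d if d >= 0 else _rshift_round_int(v, -d)
    if clamp:
        out = max(-128, min(127, out))
    return out


def infer_int8_bigint(qnet, x_codes: np.ndarray) -> np.ndarray:
    """Python-integer (unbounded precision) reimplementation of the int8
    engine, used to prove the 32-bit accumulator never silently overflows.

    Supports the layer vocabulary of the quantized networks the tests build:
    conv/deconv/classifier, relu, maxpool, concat.
    """
    from unetq.quantize import QuantizedLayer

    acts = {"input": x_codes.astype(object)}
    schemes = {"input": qnet.input_scheme.shift_bits}
    for lay in qnet.layers:
        xs = [acts[s] for s in lay.inputs]
        if isinstance(lay, QuantizedLayer):
            src = lay.inputs[0]
            x = np.empty_like(xs[0])
            for idx in np.ndindex(xs[0].shape):
                x[idx] = _rescale_int(int(xs[0][idx]), schemes[src],
                                      lay.input_scheme.shift_bits)
            if lay.transposed:
                acc = deconv3d_scatter(x, lay.weights.astype(object),
                                       lay.stride, lay.padding)
            else:
                acc = conv3d_loops(x, lay.weights.astype(object),
                                   lay.stride, lay.padding)
            acc = np.asarray(acc, dtype=object)
            out = np.empty_like(acc)
            acc_shift = lay.weight_scheme.shift_bits + lay.input_scheme.shift_bits
            for idx in np.ndindex(acc.shape):
                o = idx[1]
                total = int(acc[idx]) + _rescale_int(
                    int(lay.bias[o]), lay.bias_scheme.shift_bits, acc_shift,
                    clamp=False)
                out[idx] = _rescale_int(total, acc_shift,
                                        lay.output_scheme.shift_bits)
            acts[lay.name] = out
        elif lay.op == "relu":
            acts[lay.name] = np.vectorize(lambda v: max(0, int(v)),
                                          otypes=[object])(xs[0])
        elif lay.op == "maxpool":
            b, c, D, H, W = xs[0].shape
            out = np.empty((b, c, D // 2, H // 2, W // 2), dtype=object)
            for idx in np.ndindex(out.shape):
                bb, cc, z, y, x_ = idx
                out[idx] = max(int(xs[0][bb, cc, 2 * z + dz, 2 * y + dy,
                                         2 * x_ + dx])
                               for dz in range(2) for dy in range(2)
                               for dx in range(2))
            acts[lay.name] = out
        elif lay.op == "concat":
            t = lay.output_scheme.shift_bits
            parts = []
            for xi, s in zip(xs, lay.inputs):
                out = np.empty_like(xi)
                for idx in np.ndindex(xi.shape):
                    out[idx] = _rescale_int(int(xi[idx]), schemes[s], t)
                parts.append(out)
            acts[lay.name] = np.concatenate(parts, axis=1)
        else:
            raise AssertionError(lay.op)
        schemes[lay.name] = lay.output_scheme.shift_bits
    last = qnet.layers[-1].name
    return np.array([[int(v) for v in row] for row in
                     acts[last].reshape(acts[last].shape[0], -1)]
                    ).reshape(acts[last].shape).astype(np.int64)


# ---------------------------------------------------------------------------
# discrete-event scheduling oracle


def schedule_events(costs, double_buffered=True):
    """Event-driven four-stage scheduler.

    ``costs`` is a list of (layer_id, cf, ld, ex, wb).  Returns per
    instruction the (start, end) of each stage.  Rules: stages of one
    instruction run in order; each stage resource serves one instruction at
    a time in instruction order; with double-buffering at most two
    instructions are in flight (instruction i may configure only after
    instruction i-2 fully retires), without it instructions run strictly
    one after another; the EX stage of an instruction may only start once
    every write-back of all earlier layers has finished.
    """
    n = len(costs)
    STAGES = ("cf", "ld", "ex", "wb")
    state = [dict(stage=0, t=None) for _ in range(n)]
    times = [dict() for _ in range(n)]
    res_free = {s: 0 for s in STAGES}
    retired = [None] * n
    t = 0
    done = 0
    while done < n:
        progressed = False
        for i in range(n):
            st = state[i]
            if st["stage"] >= 4:
                continue
            stage = STAGES[st["stage"]]
            # readiness conditions
            if stage == "cf":
                ready = 0
                if double_buffered:
                    if i >= 2:
                        if retired[i - 2] is None:
                            continue
                        ready = retired[i - 2]
                else:
                    if i >= 1:
                        if retired[i - 1] is None:
                            continue
                        ready = retired[i - 1]
            else:
                prev = STAGES[st["stage"] - 1]
                ready = times[i][prev][1]
            if stage == "ex":
                lid = costs[i][0]
                wbs = [times[j]["wb"][1] for j in range(n)
                       if costs[j][0] < lid and "wb" in times[j]]
                if any(costs[j][0] < lid and "wb" not in times[j]
                       for j in range(n)):
                    continue  # an earlier layer's wb not even scheduled yet
                ready = max([ready] + wbs)
            # resource must be granted in instruction order
            if any(state[j]["stage"] == st["stage"] for j in range(i)):
                continue
            start = max(ready, res_free[stage])
            dur = costs[i][1 + st["stage"]]
            times[i][stage] = (start, start + dur)
            res_free[stage] = start + dur
            st["stage"] += 1
            if st["stage"] == 4:
                retired[i] = times[i]["wb"][1]
                done += 1
            progressed = True
        if not progressed:
            raise AssertionError("scheduling oracle deadlocked")
    return times
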