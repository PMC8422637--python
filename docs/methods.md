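# Methods

This note documents the models, conventions and numerical choices behind
`unetq`: what is computed, which decisions were genuinely open, and what
passing the test suite does and does not demonstrate.

## Network model

The network is a configurable 3D U-Net: an analysis path of two
conv(3×3×3, zero-padding 1)–BN–ReLU blocks per resolution level with
2×2×2/stride-2 max pooling between levels, and a synthesis path of
2×2×2/stride-2 deconvolutions (each followed by BN–ReLU), a concatenation
with the matching encoder level, and two further conv–BN–ReLU blocks.
Channel counts double per level (`channels_base · 2^level`); a 1×1×1
convolution maps first-level features to class scores.  Labels are the
per-voxel argmax of the scores with ties to the lowest class — scores are
monotone under softmax, so probabilities are never materialized.

Conventions that had to be fixed and are used everywhere:

* axis order `(batch, channel, depth, height, width)`;
* weights stored `(out_ch, in_ch, kd, kh, kw)` for conv **and** deconv;
* "same" padding (1) for 3×3×3 convolutions, so encoder/decoder resolutions
  match without cropping;
* deconvolution = zero-insertion upsampling + convolution with the
  spatially flipped kernel, kernel 2, stride 2, no padding ⇒ exact doubling
  of every spatial axis;
* concatenation lists the skip connection first, the upsampled branch
  second;
* input spatial axes must be divisible by `2^(depth_levels−1)`, checked at
  inference time.

The classifier head width is configurable; the synthetic study uses two
classes (background / tumor).

## BN folding

`W_merged = W·γ/√(σ²+ε)` and `B_merged = (B−μ)·γ/√(σ²+ε) + β` per output
channel.  The `+β` term is what makes the folded layer reproduce
conv-then-BN exactly, and that equivalence — not the printed formula — is
the contract the tests enforce (≤ 1e−5 relative over random triples, conv
and deconv alike).  Folding requires every BN to be the sole consumer of a
directly preceding conv/deconv; anything else raises a structural error
rather than silently skipping.  `ε` defaults to 1e−5 when absent from a
stored record; at that scale the result is insensitive to it.

## Quantization

Per-tensor dynamic fixed-point with power-of-two scales (`b_s` shift bits,
bit width 8).  Decisions worth recording:

* **Rounding** is round-half-away-from-zero for quantization and for every
  requantization shift — the arithmetic-shift-plus-offset idiom hardware
  uses.  Implemented as `sign(v)·((|v| + 2^(s−1)) >> s)`.
* **All-zero tensors** get `b_s = b_w − 1`; any scale represents zero
  exactly and `log₂ 0` never arises.
* **Exact powers of two**: `max|W| = 2^k` makes `max|W|·2^{b_s} = 128`,
  which saturates to 127.  The scale rule is followed literally; only the
  extreme element saturates, and only by half a step.
* **Accumulator**: 32-bit signed.  The bias is quantized to int8 at its own
  scale, then shifted to the accumulator scale `b_s(W)+b_s(in)` before
  addition.  The engine raises `AccumulatorOverflow` instead of wrapping,
  and a Python-integer (unbounded-precision) reimplementation in the test
  suite confirms the bound is never hit for the networks exercised.
* **Schemes are per-tensor, not per-channel**; one scale per weight tensor,
  one per bias, one per layer input and output.  ReLU and max-pooling
  preserve their input scheme; concatenation requantizes both branches to
  the coarser (smaller `b_s`) scheme, which cannot overflow.
* **Calibration** runs the *float* folded network over the calibration
  volumes and records per-layer running max |input| / |output|; the
  synthetic study calibrates on two volumes, mirroring a two-patient
  calibration set.

## 3D→2D decomposition

A `kd×kh×kw` kernel splits into `kd` 2D kernels, one per depth offset; the
3D result is their accumulated 2D convolutions, slice 0 fully accumulated
before slice 1 (the accelerator's per-block order).  Integer addition is
associative, so the decomposed path is bit-identical to direct 3D
convolution; the integer engine routes all convolutions through it.
Deconvolution reuses the same path after zero-insertion.

## Accelerator model

Layer-by-layer execution: all blocks of one layer complete (write-back)
before the next layer executes, with load prefetch allowed across the
boundary.  Within a layer:

* **Partitioning** is a deterministic greedy refinement: the output-channel
  group is halved until the block's parameters fit the parameter memory,
  then the largest spatial extent is halved (depth, height, width on ties)
  until the input region and output tile fit.  Blocks tile the output
  exactly and are ordered channel-group-major, then z, y, x.  Each of the
  three data memories is split into two ping-pong halves, so a block may
  use at most half a capacity; the allocator alternates consecutive blocks
  between the halves, giving disjoint double-buffered regions by
  construction.
* **PE modes** 4-32 / 32-32 / 32-64 (input×output channel parallelism)
  compute 4 / 2 / 1 feature-map pixels per issue.  Layers whose channel
  counts miss a mode are zero-padded to the nearest one; padded lanes count
  as issued-but-idle in the occupancy report.
* **Cycle model**: `EX = padded MACs / mode lanes`, `LD`/`WB` =
  `ceil(bytes / bandwidth)`, `CF` a fixed per-instruction configuration
  cost.  No absolute cycle counts are claimed — coefficients live in
  `ResourceConfig` (YAML) and the model is validated through its
  invariants: double-buffered makespan ≤ serial makespan always; with
  uniform costs and dominant EX (`e ≥ c+l+w`) the makespan is exactly
  `c + l + N·e + w`; every trace matches an independent discrete-event
  simulator.  CF is issued per block.
* **Zero-block skipping** tests each block's required input region (in
  padded, zero-inserted coordinates) for all-zero; skipped blocks emit no
  instruction and their output is the requantized bias-only value — which
  is precisely what convolving a zero region yields, so the skipped
  schedule is bit-identical to the full one.  Detection is per block, not
  per pixel.
* **Instruction format**: little-endian fixed-width records (opcode, PE
  mode, layer id, four stage costs, four addresses, true/padded MAC
  counts) behind a versioned 10-byte header; round-trip tested.  ReLU,
  pooling and concatenation are treated as fused/free and generate no
  instructions; only conv/deconv blocks are scheduled.

## Synthetic data

A phantom emulates a skull-stripped 4-modality case on a 16³ grid (32³ in
some tests): the "brain" is the k nearest voxels to the centre, with k set
so the exactly-zero exterior hits the requested zero fraction (default
70%, the typical sparsity of skull-stripped brain volumes).  Brain tissue
draws from per-modality background profiles (clipped above zero so only
the exterior is exactly zero); 2 spherical tumor blobs of radius 3–5
voxels with a smooth intensity ramp over the outer 30% of `r²` draw from
distinct tumor profiles.  Labels mark blob voxels inside the brain.

What the phantoms deliberately do not model: MRI physics (bias fields,
Rician noise), inter-subject anatomy, multi-class tumor substructure, and
real tumor morphology.  Passing tests therefore demonstrate the
correctness of the arithmetic and scheduling, and that quantization
degrades a *learnable* segmentation task by only a few thousandths of a
Dice point — not clinical-grade accuracy on real data.

`fit_toy` is a fixture, not a trainer: full-batch gradient descent
(lr 0.05, momentum 0.9) on a class-weighted softmax cross-entropy
(inverse-frequency weights keep the ~9%-of-voxels foreground from being
ignored), applied to the BN-folded network.  If a run of the step budget
stalls below the requested held-out Dice floor (0.8 in the study), the
parameters are re-initialized deterministically from the seed and fitting
restarts, up to three times; failure after that raises instead of
returning a bad fixture.  Problem sizes (16³ volumes, 4 training / 10
held-out phantoms, base width 4, two levels, ≤ 300 steps per run) were
chosen to make the full study a sub-minute computation.

## Known limitations

* Per-tensor scales only; per-channel quantization and quantization-aware
  retraining are out of scope.
* The cycle model is parametric, not calibrated against hardware; use it
  for relative comparisons (double-buffering on/off, skipping on/off,
  partition choices), not wall-clock predictions.
* The partitioner's capacity-monotonicity (smaller memory never yields
  fewer blocks) holds for the halving refinement used here; it is a
  property of this scheme, not of arbitrary partitioners.
* NIfTI affines are passed through untouched; no resampling or
  registration is performed.
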