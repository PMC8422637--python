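# unetq

Post-training **int8 quantization** and a **bit-exact fixed-point inference
simulator** for 3D U-Net-style brain-tumor segmentation networks, plus a
cycle-approximate model of a block-partitioned, double-buffered FPGA
accelerator.

Deep 3D segmentation networks for multi-modality MRI (flair, t1, t2, t1ce)
are accurate but expensive; deploying them on fixed-point hardware requires
(i) removing batch-normalization layers, (ii) replacing float tensors with
8-bit codes and power-of-two scale factors, and (iii) scheduling the
computation through limited on-chip memory.  `unetq` implements that whole
flow in software so the quantization mathematics and the scheduling logic
can be developed, verified and regression-tested without hardware or
clinical data.  Its audience is engineers building fixed-point inference
paths for volumetric medical imaging, and anyone who needs a reproducible
reference for dynamic fixed-point arithmetic.

## The model

**BN folding.** At inference a BN layer is a per-channel affine map; it
merges into the preceding convolution (or deconvolution):

```
W_merged = W · γ / √(σ² + ε)
B_merged = (B − μ) · γ / √(σ² + ε) + β
```

so `Y = W_merged · X + B_merged` reproduces conv-then-BN exactly.

**Dynamic fixed-point quantization.** Every tensor is stored as int8 codes
with a power-of-two scale `2^b_s` chosen from its max absolute value:

```
b_s = b_w − 1 − ceil(log₂ max|W|),   b_w = 8
q   = clamp(round(x · 2^b_s), −128, 127)
```

Weight and bias scales are computed per layer; activation scales come from a
calibration pass (a couple of representative volumes run through the float
network, recording per-layer max |input| and |output|).  Scaling is a bit
shift on hardware — that is the point of the power-of-two constraint.

**Integer engine.** int8×int8 products accumulate in a 32-bit signed
accumulator at scale `b_s(W)+b_s(in)`; the bias is shifted to that scale,
the sum is rescaled to the output scheme by an arithmetic shift with
round-half-away-from-zero, then clamped.  The result is bit-reproducible,
and every 3D convolution is computed as an accumulation of 2D depth-slice
convolutions — exactly as a 2D PE array does it, and exactly equal to direct
3D convolution for integer inputs.

**Accelerator model.** Layers are partitioned into computation blocks that
fit on-chip memory; one four-stage instruction (CF / LD / EX / WB) per
block; double-buffering overlaps consecutive instructions so the longest
stage hides the others; blocks whose entire input region is zero (common
after the zero-insertion of deconvolution, and in the empty exterior of
brain volumes) are skipped and replaced by their bias-only output, which
leaves the result bit-identical.

## Worked example

```bash
unetq make-fixtures --out cases --n-volumes 2 --seed 3 \
      --net-out net.npz --channels-base 2
unetq fold --net net.npz --out folded.npz
unetq quantize --net folded.npz --calib cases/phantom000 \
      --calib cases/phantom001 --out qnet.npz
unetq simulate --qnet qnet.npz --in cases/phantom000 --out lab.nii.gz
```

The simulate step prints, for a 16³ phantom with a 70% zero background:

```
label volume written to lab.nii.gz
makespan=127928 cycles, blocks=8, skipped=0 (0.0%)
```

With tighter memories (a resources YAML containing `input_mem: 512` and
`output_mem: 512`) the same network tiles into many small blocks, and the
all-zero ones are skipped:

```
makespan=118929 cycles, blocks=1920, skipped=146 (7.6%)
```

The label volume is the argmax over the classifier's int8 codes and is
bit-identical to `unetq infer --mode int8` for every partition.  The
network archive here carries *random* weights — the pipeline mechanics, not
segmentation quality, are the point of the example; a network that actually
segments the phantoms is produced by `unetq.synthetic.fit_toy` (as the
acceptance script does).  `unetq evaluate --pred ... --ref ...` prints the
per-class Dice table for any two label volumes.

In Python the same flow is `fold_network` → `calibrate` → `quantize_network`
→ `infer_int8` / `run_accelerated`; see `docs/methods.md` for the precise
arithmetic and the scheduling rules.

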