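"""Synthetic test data: brain-like phantoms, random networks, toy fitting.

Everything tests and examples need is generated here, deterministically from
a seed, with no external downloads.

A phantom emulates a skull-stripped 4-modality MRI case: outside a roughly
spherical "brain" region every voxel of every modality is exactly zero (the
air background of BraTS-style volumes, the source of their ~70% sparsity);
inside the brain, voxels draw from per-modality background-tissue intensity
profiles, and a few spherical "tumor" blobs with smooth intensity falloff
draw from distinct tumor profiles.  The brain mask is the k nearest voxels
to the volume centre with k chosen to hit the requested zero fraction
exactly, so the zero fraction is controllable and the zero region is
contiguous — which is what makes whole computation blocks skippable.

The toy fitting helper adjusts the convolution parameters of a (BN-folded)
network by full-batch gradient descent on a voxelwise softmax cross-entropy.
It exists to give end-to-end tests a network that actually segments the
phantoms; it is not a training framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ops
from .errors import FitError, ShapeError, UnetqError
from .folding import fold_network
from .layers import (MODALITIES, PARAM_OPS, BNParams, NetworkGraph, Triple,
                     Volume)
from .metrics import dice
from .network import argmax_labels, build_unet3d, forward_activations, infer_float


@dataclass
class PhantomSpec:
    """Parameters of one synthetic 4-modality volume."""

    shape: Triple = (16, 16, 16)
    n_blobs: int = 2
    blob_radius: tuple[float, float] = (3.0, 5.0)
    blob_edge: float = 0.3  # fraction of r^2 over which intensity falls off
    tumor_mean: tuple = (0.95, 0.75, 0.9, 1.0)
    tumor_sd: float = 0.06
    background_mean: tuple = (0.4, 0.45, 0.35, 0.3)
    background_sd: float = 0.08
    zero_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.zero_fraction < 1:
            raise UnetqError("zero_fraction must be in [0, 1)")
        if len(self.tumor_mean) != len(MODALITIES) or \
                len(self.background_mean) != len(MODALITIES):
            raise UnetqError("one intensity mean per modality is required")


def make_phantom(spec: PhantomSpec) -> tuple[Volume, Volume]:
    """Generate a (4-channel volume, label volume) pair from the spec."""
    rng = np.random.default_rng(spec.seed)
    D, H, W = spec.shape
    n = D * H * W
    zz, yy, xx = np.meshgrid(np.arange(D), np.arange(H), np.arange(W),
                             indexing="ij")
    centre = ((D - 1) / 2, (H - 1) / 2, (W - 1) / 2)
    dist = np.sqrt((zz - centre[0]) ** 2 + (yy - centre[1]) ** 2
                   + (xx - centre[2]) ** 2)
    # brain mask: the k nearest voxels to the centre -> exact zero fraction
    k = int(round((1.0 - spec.zero_fraction) * n))
    if k < 1:
        raise UnetqError("zero_fraction leaves no brain voxels")
    order = np.argsort(dist, axis=None, kind="stable")
    brain = np.zeros(n, dtype=bool)
    brain[order[:k]] = True
    brain = brain.reshape(spec.shape)
    brain_radius = float(dist.reshape(-1)[order[k - 1]])

    rmin, rmax = spec.blob_radius
    if rmax >= min(spec.shape) / 2 or rmax >= brain_radius:
        raise UnetqError(
            f"blob radius up to {rmax} cannot fit a {spec.shape} phantom "
            f"with brain radius {brain_radius:.1f}")
    tumor_w = np.zeros(spec.shape)
    label = np.zeros(spec.shape, dtype=np.int16)
    for _ in range(spec.n_blobs):
        r = rng.uniform(rmin, rmax)
        # place the blob centre well inside the brain sphere
        for _attempt in range(1000):
            c = np.array(centre) + rng.uniform(-1, 1, size=3) * \
                max(brain_radius - r, 0.0) / np.sqrt(3.0)
            if np.all(c - r >= -0.5) and np.all(c + r <= np.array(spec.shape) - 0.5):
                break
        else:
            raise UnetqError("could not place a blob inside the phantom")
        d2 = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) / r ** 2
        # full tumor intensity in the core, smooth ramp near the boundary
        tumor_w = np.maximum(
            tumor_w, np.clip((1.0 - d2) / max(spec.blob_edge, 1e-6), 0.0, 1.0))
        label[(d2 <= 1.0) & brain] = 1

    chans = []
    for m, (bg_mu, tu_mu) in enumerate(zip(spec.background_mean,
                                           spec.tumor_mean)):
        bg = rng.normal(bg_mu, spec.background_sd, size=spec.shape)
        tu = rng.normal(tu_mu, spec.tumor_sd, size=spec.shape)
        img = bg * (1.0 - tumor_w) + tu * tumor_w
        img = np.clip(img, 0.02, None)  # brain tissue is never exactly zero
        img[~brain] = 0.0
        chans.append(img)
    vol = Volume(data=np.stack(chans)[None], value_kind="real",
                 affine=np.eye(4))
    lab = Volume(data=label[None, None], value_kind="real", affine=np.eye(4))
    return vol, lab


def make_random_network(channels_base: int, depth_levels: int, seed: int,
                        in_channels: int = 4, out_classes: int = 2
                        ) -> NetworkGraph:
    """A U-Net-topology graph with seeded random weights and BN statistics.

    Weights are scaled by fan-in (He-style) so activations stay bounded;
    BN statistics are drawn near the identity map (variance in [0.8, 1.2],
    gain in [0.9, 1.1]) so folding is well-conditioned.
    """
    rng = np.random.default_rng(seed)
    net = build_unet3d(channels_base, depth_levels, in_channels, out_classes)
    for lay in net.layers:
        if lay.op in PARAM_OPS:
            w = lay.conv.weights
            fan_in = w.shape[1] * w.shape[2] * w.shape[3] * w.shape[4]
            lay.conv.weights = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=w.shape)
            lay.conv.bias = rng.normal(0.0, 0.01, size=lay.conv.bias.shape)
        elif lay.op == "bn":
            ch = lay.bn.channels
            lay.bn = BNParams(
                mean=rng.normal(0.0, 0.05, size=ch),
                var=rng.uniform(0.8, 1.2, size=ch),
                gamma=rng.uniform(0.9, 1.1, size=ch),
                beta=rng.normal(0.0, 0.05, size=ch))
    return net


# ---------------------------------------------------------------------------
# toy fitting


def _softmax_ce_grad(scores: np.ndarray, labels: np.ndarray,
                     class_weights: np.ndarray | None = None
                     ) -> tuple[float, np.ndarray]:
    """Voxelwise softmax cross-entropy loss and its gradient wrt scores.

    With ``class_weights`` each voxel contributes proportionally to its true
    class's weight; inverse-frequency weights keep a small foreground (a few
    percent of tumor voxels) from being drowned out by the background.
    """
    s = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(s)
    p = e / e.sum(axis=1, keepdims=True)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels.astype(np.intp), 1.0, axis=1)
    if class_weights is None:
        class_weights = np.ones(scores.shape[1])
    wv = (onehot * class_weights.reshape(1, -1, 1, 1, 1)).sum(
        axis=1, keepdims=True)
    norm = float(wv.sum())
    logp = np.log(np.clip(p, 1e-12, None))
    loss = float(-(wv * (onehot * logp).sum(axis=1, keepdims=True)).sum() / norm)
    return loss, wv * (p - onehot) / norm


def _backward(net: NetworkGraph, acts: dict[str, np.ndarray],
              gscores: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Gradients of the loss wrt every conv layer's (weights, bias)."""
    grads: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    gact: dict[str, np.ndarray] = {net.layers[-1].name: gscores}
    for lay in reversed(net.layers):
        gy = gact.pop(lay.name, None)
        if gy is None:
            continue
        xs = [acts[s] for s in lay.inputs]
        if lay.op in ("conv", "classifier"):
            gx, gw, gb = ops.conv3d_backward(
                xs[0], lay.conv.weights, gy, lay.conv.stride, lay.conv.padding)
            grads[lay.name] = (gw, gb)
            gins = [gx]
        elif lay.op == "deconv":
            gx, gw, gb = ops.deconv3d_backward(
                xs[0], lay.conv.weights, gy, lay.conv.stride, lay.conv.padding)
            grads[lay.name] = (gw, gb)
            gins = [gx]
        elif lay.op == "relu":
            gins = [gy * (acts[lay.name] > 0)]
        elif lay.op == "maxpool":
            gins = [ops.maxpool2_backward(xs[0], gy)]
        elif lay.op == "concat":
            c0 = xs[0].shape[1]
            gins = [gy[:, :c0], gy[:, c0:]]
        else:
            raise UnetqError(f"cannot backpropagate through op {lay.op!r}")
        for src, g in zip(lay.inputs, gins):
            if src == "input":
                continue
            gact[src] = gact[src] + g if src in gact else g
    return grads


def fit_toy(net: NetworkGraph, phantoms: list[tuple[Volume, Volume]],
            steps: int, seed: int, *, lr: float = 0.05, momentum: float = 0.9,
            dsc_floor: float | None = None,
            holdout: list[tuple[Volume, Volume]] | None = None,
            class_id: int = 1, check_every: int = 10,
            max_restarts: int = 3) -> NetworkGraph:
    """Full-batch gradient descent on a class-weighted voxelwise
    cross-entropy.

    BN layers, if present, are folded first (the toy objective trains the
    merged convolution parameters directly).  With ``steps=0`` the network
    is returned unchanged.  When ``dsc_floor`` and ``holdout`` are given,
    fitting stops early once the held-out Dice score for ``class_id``
    reaches the floor; if a run of ``steps`` steps stalls below the floor
    the parameters are re-initialized (deterministically from ``seed``) and
    fitting restarts, up to ``max_restarts`` times.  A :class:`FitError` is
    raised if the floor is never reached — the fixture contract for
    end-to-end tests.
    """
    net = fold_network(net) if any(l.op == "bn" for l in net.layers) else net.copy()
    if steps == 0:
        return net
    if not phantoms:
        raise UnetqError("fit_toy needs at least one training phantom")
    x = np.concatenate([np.asarray(v.data, dtype=np.float64)
                        for v, _ in phantoms], axis=0)
    y = np.concatenate([np.asarray(l.data) for _, l in phantoms], axis=0)
    if x.shape[2:] != y.shape[2:]:
        raise ShapeError("phantom volumes and labels must share spatial shape")

    def holdout_dsc(g: NetworkGraph) -> float:
        scores = [dice(argmax_labels(infer_float(g, v)).data, l.data, class_id)
                  for v, l in holdout]
        return float(np.mean(scores))

    freq = np.array([(y == c).mean() for c in range(net.out_classes)])
    weights = 1.0 / np.maximum(freq, 1e-6)
    weights /= weights.sum()

    check = dsc_floor is not None and holdout
    best, best_dsc = net, -1.0
    for attempt in range(max_restarts + 1):
        if attempt > 0:
            rng = np.random.default_rng([seed, attempt])
            for lay in net.layers:
                if lay.op in PARAM_OPS:
                    w = lay.conv.weights
                    fan_in = int(np.prod(w.shape[1:]))
                    lay.conv.weights = rng.normal(
                        0.0, np.sqrt(2.0 / fan_in), size=w.shape)
                    lay.conv.bias = rng.normal(0.0, 0.01,
                                               size=lay.conv.bias.shape)
        vel: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for step in range(1, steps + 1):
            acts = forward_activations(net, x)
            _, gscores = _softmax_ce_grad(acts[net.layers[-1].name], y, weights)
            grads = _backward(net, acts, gscores)
            for lay in net.layers:
                if lay.op not in PARAM_OPS:
                    continue
                gw, gb = grads[lay.name]
                vw, vb = vel.get(lay.name,
                                 (np.zeros_like(gw), np.zeros_like(gb)))
                vw = momentum * vw - lr * gw
                vb = momentum * vb - lr * gb
                vel[lay.name] = (vw, vb)
                lay.conv.weights = lay.conv.weights + vw
                lay.conv.bias = lay.conv.bias + vb
            if check and (step % check_every == 0 or step == steps):
                if holdout_dsc(net) >= dsc_floor:
                    return net
        if not check:
            return net
        d = holdout_dsc(net)
        if d > best_dsc:
            best, best_dsc = net.copy(), d
    raise FitError(
        f"held-out DSC {best_dsc:.3f} below the required floor "
        f"{dsc_floor} after {max_restarts + 1} runs of {steps} steps")
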