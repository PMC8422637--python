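"""Segmentation evaluation: Dice similarity coefficient and pixel accuracy.

DSC for one class c is 2|A∩B| / (|A|+|B|) over the binary masks A = {pred=c}
and B = {ref=c}; when both masks are empty the score is defined as 1.0
(standard convention, avoids 0/0).  Pixel accuracy is the fraction of voxels
whose labels agree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ShapeError
from .layers import Volume


def _as_labels(x) -> np.ndarray:
    if isinstance(x, Volume):
        x = x.data
    return np.asarray(x)


def _check_pair(pred: np.ndarray, ref: np.ndarray) -> None:
    if pred.shape != ref.shape:
        raise ShapeError(
            f"prediction shape {pred.shape} != reference shape {ref.shape}"
        )


def dice(pred, ref, class_id: int = 1) -> float:
    """Dice similarity coefficient of one class: 2*TP / (2*TP + FP + FN)."""
    pred, ref = _as_labels(pred), _as_labels(ref)
    _check_pair(pred, ref)
    a = pred == class_id
    b = ref == class_id
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def pixel_accuracy(pred, ref) -> float:
    """Fraction of voxels with identical labels."""
    pred, ref = _as_labels(pred), _as_labels(ref)
    _check_pair(pred, ref)
    return float((pred == ref).mean())


def dice_per_class(pred, ref, n_classes: int | None = None) -> pd.DataFrame:
    """Per-class DSC table plus the unweighted mean over classes.

    Classes are 0..n_classes-1; when n_classes is omitted it is inferred
    from the labels present in either volume.
    """
    pred, ref = _as_labels(pred), _as_labels(ref)
    _check_pair(pred, ref)
    if n_classes is None:
        n_classes = int(max(pred.max(initial=0), ref.max(initial=0))) + 1
    rows = [{"class": c,
             "dice": dice(pred, ref, c),
             "pred_voxels": int((pred == c).sum()),
             "ref_voxels": int((ref == c).sum())}
            for c in range(n_classes)]
    df = pd.DataFrame(rows)
    df.loc[len(df)] = {"class": "mean", "dice": df["dice"].mean(),
                       "pred_voxels": int(pred.size), "ref_voxels": int(ref.size)}
    return df
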