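"""NIfTI volume I/O.

A 4-modality case is four single-modality NIfTI files merged on the channel
axis in the fixed order flair, t1, t2, t1ce (the BraTS layout).  Affines and
headers are passed through unmodified — the package does no spatial
resampling — and synthetic fixtures use identity affines.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ShapeError, UnetqError
from .layers import MODALITIES, Volume


def _read_one(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise UnetqError(f"input file does not exist: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3D volume, got {data.ndim} axes")
    return data, np.asarray(img.affine)


def load_volume(paths) -> Volume:
    """Load one or more single-modality NIfTI files as a (1, C, D, H, W) volume.

    ``paths`` may be a single path, a sequence of paths (channel order as
    given), or a directory containing ``<modality>.nii.gz`` files for the
    four canonical modalities.
    """
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        d = Path(paths)
        paths = [_find_modality(d, m) for m in MODALITIES]
    elif isinstance(paths, (str, Path)):
        paths = [paths]
    chans, affine = [], None
    for p in paths:
        data, aff = _read_one(p)
        if affine is None:
            affine = aff
        if chans and data.shape != chans[0].shape:
            raise ShapeError(f"{p}: modality shapes differ")
        chans.append(data)
    return Volume(data=np.stack(chans)[None, ...], value_kind="real",
                  affine=affine)


def _find_modality(d: Path, modality: str) -> Path:
    for suffix in (".nii.gz", ".nii"):
        p = d / f"{modality}{suffix}"
        if p.exists():
            return p
    raise UnetqError(f"no {modality} NIfTI file in {d}")


def load_labels(path) -> Volume:
    """Load an integer label map as a (1, 1, D, H, W) volume."""
    data, affine = _read_one(path)
    return Volume(data=np.rint(data).astype(np.int16)[None, None],
                  value_kind="real", affine=affine)


def save_labels(vol: Volume, path) -> None:
    """Write a single-channel label/score volume as one NIfTI file."""
    if vol.data.shape[0] != 1 or vol.data.shape[1] != 1:
        raise ShapeError("save_labels expects a (1, 1, D, H, W) volume")
    affine = vol.affine if vol.affine is not None else np.eye(4)
    arr = np.asarray(vol.data[0, 0])
    if arr.dtype == np.int8:
        arr = arr.astype(np.int16)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def save_modalities(vol: Volume, directory, names=MODALITIES) -> list[Path]:
    """Write each channel of a volume as one single-modality NIfTI file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if vol.data.shape[1] != len(names):
        raise ShapeError(
            f"volume has {vol.data.shape[1]} channels but {len(names)} "
            f"modality names were given"
        )
    affine = vol.affine if vol.affine is not None else np.eye(4)
    paths = []
    for i, name in enumerate(names):
        p = directory / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol.data[0, i], dtype=np.float64),
                                 affine), str(p))
        paths.append(p)
    return paths
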