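"""NIfTI / PNG / CSV input-output with JSON sidecars.

Images are written as NIfTI with the voxel spacing encoded in the affine
(millimetres, for viewers) and, authoritatively, in a JSON sidecar in
micrometres so spacing survives round trips bit-exactly.  Masks ride along
as a second NIfTI; label rasters carry their label dictionary in the
sidecar.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import LABEL_NAMES, IntensityVolume, LabelMap

IMAGE_SUFFIXES = (".nii", ".nii.gz")


def _affine(spacing_um: tuple[float, ...]) -> np.ndarray:
    diag = [s / 1000.0 for s in spacing_um]
    while len(diag) < 3:
        diag.append(1.0)
    return np.diag(diag + [1.0])


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in IMAGE_SUFFIXES:
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    raise ValueError(
        f"unsupported image extension on {path.name!r}; supported: {IMAGE_SUFFIXES}"
    )


def _mask_path(path: Path) -> Path:
    name = path.name
    for suf in IMAGE_SUFFIXES:
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + "_mask" + suf)
    raise ValueError(f"unsupported image extension on {path.name!r}")


def write_image(vol: IntensityVolume, path: str | Path) -> Path:
    """Write intensities (float32), mask (uint8), and a spacing sidecar."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)  # validates the extension up front
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.spacing)), path)
    nib.save(
        nib.Nifti1Image(vol.mask.astype(np.uint8), _affine(vol.spacing)),
        _mask_path(path),
    )
    sidecar = {"spacing_um": list(vol.spacing), "kind": "intensity"}
    sidecar_file.write_text(json.dumps(sidecar, indent=2))
    return path


def read_image(path: str | Path) -> IntensityVolume:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    sidecar = json.loads(_sidecar_path(path).read_text())
    spacing = tuple(sidecar["spacing_um"])
    mask_file = _mask_path(path)
    mask = None
    if mask_file.exists():
        mask = np.asarray(nib.load(mask_file).dataobj) > 0
    return IntensityVolume(data, spacing, mask)


def write_labels(lmap: LabelMap, path: str | Path) -> Path:
    """Write a label raster (uint8) with its label dictionary sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(lmap.labels.astype(np.uint8), _affine(lmap.spacing)), path)
    sidecar = {
        "spacing_um": list(lmap.spacing),
        "kind": "labels",
        "labels": {str(k): v for k, v in lmap.label_names.items()},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_labels(path: str | Path) -> LabelMap:
    path = Path(path)
    img = nib.load(path)
    labels = np.asarray(img.dataobj).astype(np.uint8)
    sidecar = json.loads(_sidecar_path(path).read_text())
    names = {int(k): v for k, v in sidecar.get("labels", {}).items()} or dict(
        LABEL_NAMES
    )
    return LabelMap(labels, tuple(sidecar["spacing_um"]), names)


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
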