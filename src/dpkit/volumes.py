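"""3-D volume I/O: NIfTI (via nibabel) and raw binary + JSON header.

Integer volumes (counts, masks) round-trip bitwise; floating volumes
(dose) are stored as 32-bit floats.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_volume", "write_volume"]


def _check_3d(arr: np.ndarray, where: str) -> np.ndarray:
    if arr.ndim != 3:
        raise ValueError(f"{where}: expected a 3-D volume, got shape {arr.shape}")
    return arr


def write_volume(path, values: np.ndarray, spacing_mm) -> None:
    """Write a 3-D volume; format chosen by extension (.nii/.nii.gz or .raw)."""
    path = Path(path)
    values = _check_3d(np.asarray(values), f"writing {path.name}")
    spacing = tuple(float(s) for s in spacing_mm)
    if np.issubdtype(values.dtype, np.floating):
        values = values.astype(np.float32)
    if path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag([*spacing, 1.0])
        nib.save(nib.Nifti1Image(values, affine), str(path))
    elif path.suffix == ".raw":
        values.tofile(path)
        header = {
            "shape": list(values.shape),
            "spacing_mm": list(spacing),
            "dtype": values.dtype.str,
            "origin": [0.0, 0.0, 0.0],
        }
        path.with_suffix(".json").write_text(json.dumps(header))
    else:
        raise ValueError(
            f"unsupported volume format {path.suffix!r} (use .nii, .nii.gz or .raw)"
        )


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3-D volume; returns (array, spacing in mm)."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
        _check_3d(arr, f"reading {path.name}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return arr, spacing
    if path.suffix == ".raw":
        header = json.loads(path.with_suffix(".json").read_text())
        arr = np.fromfile(path, dtype=np.dtype(header["dtype"]))
        arr = arr.reshape(header["shape"])
        _check_3d(arr, f"reading {path.name}")
        return arr, tuple(float(s) for s in header["spacing_mm"])
    raise ValueError(
        f"unsupported volume format {path.suffix!r} (use .nii, .nii.gz or .raw)"
    )
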