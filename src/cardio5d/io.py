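"""File I/O: NIfTI masks and dose grids, signal/trigger CSVs, result tables.

Volumes are stored RAS+ (x = right, y = anterior, z = superior), which
matches the package's RL/AP/SI sign convention directly.  On read, files in
other axis-aligned orientations are reoriented to canonical RAS; oblique
affines are rejected with an explicit error.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dosimetry import DoseGrid
from .errors import GeometryError, ParameterError
from .structures import StructureMask


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _load_canonical(path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-4):
        raise GeometryError(
            f"{path}: oblique affine cannot be mapped onto the RL/AP/SI axes"
        )
    spacing = tuple(float(s) for s in np.diag(rot))
    if any(s <= 0 for s in spacing):
        raise GeometryError(f"{path}: non-positive voxel spacing {spacing}")
    origin = tuple(float(o) for o in aff[:3, 3])
    data = np.asarray(img.dataobj)
    return data, spacing, origin


def write_mask(mask: StructureMask, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    nib.save(img, str(path))
    return path


def read_mask(path, label: str | None = None) -> StructureMask:
    data, spacing, origin = _load_canonical(path)
    rounded = np.round(data)
    if not np.isin(np.unique(rounded), (0, 1)).all() or np.abs(data - rounded).max() > 1e-6:
        raise ParameterError(f"{path}: volume is not a binary mask")
    return StructureMask(rounded.astype(bool), spacing, origin, label=label)


def write_dose(dose: DoseGrid, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(dose.values.astype(np.float32), _affine(dose.spacing, dose.origin))
    nib.save(img, str(path))
    return path


def read_dose(path) -> DoseGrid:
    data, spacing, origin = _load_canonical(path)
    return DoseGrid(np.asarray(data, dtype=float), spacing, origin)


def write_signal(times: np.ndarray, values: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": times, "amplitude": values}).to_csv(path, index=False)
    return path


def read_signal(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if not {"time_s", "amplitude"} <= set(df.columns):
        raise ParameterError(f"{path}: expected columns time_s, amplitude")
    return df["time_s"].to_numpy(float), df["amplitude"].to_numpy(float)


def write_triggers(trigger_times: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"trigger_time_s": trigger_times}).to_csv(path, index=False)
    return path


def read_triggers(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "trigger_time_s" not in df.columns:
        raise ParameterError(f"{path}: expected column trigger_time_s")
    return df["trigger_time_s"].to_numpy(float)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def mask_filename(substructure: str, cardiac: str, resp: str) -> str:
    """Canonical mask filename encoding substructure and phase."""
    return f"mask_{substructure}_{cardiac}_{resp}.nii"
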