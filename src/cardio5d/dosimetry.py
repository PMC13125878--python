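"""DVH computation and near-maximum dose metrics (D_v, e.g. D_0.03cc).

Doses are sampled by trilinear interpolation at mask voxel centers (exact on
linear fields).  D_v is computed from the sorted per-voxel dose list with
fractional-voxel interpolation, independent of any DVH binning resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import (
    EmptyStructureError,
    GeometryError,
    GridMismatchError,
    ParameterError,
    UndefinedMetricError,
)
from .structures import StructureMask


@dataclass
class DoseGrid:
    """3D dose in Gy on a regular grid (same axis convention as masks)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise GeometryError(f"dose grid must be 3D, got shape {values.shape}")
        if not np.isfinite(values).all():
            raise ParameterError("dose values must be finite")
        if (values < 0).any():
            raise ParameterError("dose values must be >= 0")
        self.values = values
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve: V(d) = volume receiving >= d."""

    dose_gy: np.ndarray
    volume_cc: np.ndarray
    volume_pct: np.ndarray


def sample_dose(structure: StructureMask, dose: DoseGrid) -> tuple[np.ndarray, float]:
    """Trilinear dose at each set-voxel center; returns (doses, voxel volume cc)."""
    if structure.is_empty:
        raise EmptyStructureError("cannot sample dose for an empty structure")
    pts = structure.voxel_coordinates()
    idx = (pts - np.asarray(dose.origin)) / np.asarray(dose.spacing)
    upper = np.asarray(dose.shape) - 1
    tol = 1e-9
    if np.any(idx < -tol) or np.any(idx > upper + tol):
        raise GridMismatchError(
            "structure extends outside the physical extent of the dose grid"
        )
    idx = np.clip(idx, 0, upper)
    doses = map_coordinates(dose.values, idx.T, order=1, mode="nearest")
    voxel_cc = structure.voxel_volume_mm3 / 1000.0
    return np.asarray(doses, dtype=float), voxel_cc


def dvh(doses: np.ndarray, voxel_volume_cc: float, bin_width_gy: float = 0.1) -> DVHCurve:
    """Cumulative DVH from per-voxel doses.

    V(0) equals the total structure volume; the curve is non-increasing.
    """
    d = np.asarray(doses, dtype=float)
    if d.size == 0:
        raise EmptyStructureError("empty dose sample list")
    if bin_width_gy <= 0:
        raise ParameterError("bin width must be > 0")
    edges = np.arange(0.0, d.max() + 2 * bin_width_gy, bin_width_gy)
    vol = np.array([(d >= e).sum() * voxel_volume_cc for e in edges])
    total = d.size * voxel_volume_cc
    return DVHCurve(dose_gy=edges, volume_cc=vol, volume_pct=100.0 * vol / total)


def d_cc(doses: np.ndarray, voxel_volume_cc: float, v_cc: float = 0.03) -> float:
    """Minimum dose of the hottest ``v_cc`` cm^3 (D_v).

    Doses are sorted descending; the cumulative-volume grid is
    ``k * voxel_volume`` after k voxels and the dose at ``v_cc`` is linearly
    interpolated across the straddling voxel.  Volumes below one voxel return
    the hottest voxel's dose.
    """
    d = np.sort(np.asarray(doses, dtype=float))[::-1]
    if d.size == 0:
        raise EmptyStructureError("empty dose sample list")
    if v_cc <= 0:
        raise ParameterError("v_cc must be > 0")
    total = d.size * voxel_volume_cc
    if total < v_cc - 1e-12:
        raise UndefinedMetricError(
            f"structure volume {total:.4f} cc is smaller than v_cc={v_cc} cc"
        )
    cum = voxel_volume_cc * np.arange(1, d.size + 1)
    return float(np.interp(v_cc, cum, d))


def structure_d_cc(structure: StructureMask, dose: DoseGrid, v_cc: float = 0.03) -> float:
    doses, voxel_cc = sample_dose(structure, dose)
    return d_cc(doses, voxel_cc, v_cc)


def delta_d(
    reference: StructureMask,
    irv: StructureMask,
    dose: DoseGrid,
    v_cc: float = 0.03,
) -> float:
    """ΔD_v = D_v(IRV) - D_v(reference); non-negative when IRV ⊇ reference."""
    if not reference.same_grid(irv):
        raise GridMismatchError("reference and IRV must share a grid")
    if np.any(reference.data & ~irv.data):
        raise ParameterError("IRV must be a superset of the reference structure")
    return structure_d_cc(irv, dose, v_cc) - structure_d_cc(reference, dose, v_cc)
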