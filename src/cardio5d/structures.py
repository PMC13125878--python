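"""Structure-mask data model and geometric reductions.

Axis convention used throughout the package (array index -> physical axis):

* axis 0 = x = right-left (RL), positive toward patient **right**
* axis 1 = y = anterior-posterior (AP), positive **anterior**
* axis 2 = z = superior-inferior (SI), positive **superior**

Physical coordinates follow the voxel-*center* convention:
``coord = origin + spacing * index`` (0-based indices).  Bounding-box face
coordinates are extreme set-voxel centers, not outer voxel edges, so that
centroid and face displacements live in a single coordinate frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

from .errors import (
    EmptyStructureError,
    GeometryError,
    GridMismatchError,
)

#: Substructure labels recognised by the cohort-level tooling.  Analyses accept
#: arbitrary labels; this set exists for validation of configured groupings.
SUBSTRUCTURE_LABELS = frozenset(
    {
        "RCA", "LMCA", "LADA", "LCX",          # coronary arteries
        "LV", "RV", "LA", "RA",                # chambers
        "AA", "DA", "PA", "PVs", "IVC", "SVC",  # great vessels
        "WH",                                   # whole heart
        "V-MV", "V-TV", "V-AV", "V-PV",        # valves (geometric model)
        "SAN", "AVN",                           # conduction nodes
    }
)

CARDIAC_PHASES = ("ED", "ES")
RESP_STATES = ("EE", "AEx", "AIn", "EI")

#: ventricle/neighbor pairings for the geometric valve model
VALVE_PAIRINGS = {
    ("LV", "LA"): "V-MV",
    ("LV", "AA"): "V-AV",
    ("RV", "RA"): "V-TV",
    ("RV", "PA"): "V-PV",
}


@dataclass
class StructureMask:
    """A single substructure at one (cardiac, respiratory) phase.

    Parameters
    ----------
    data:
        3D boolean array; ``data[i, j, k]`` indexes (RL, AP, SI).
    spacing:
        Voxel spacing in mm per axis, all strictly positive.
    origin:
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    label:
        Optional substructure label.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise GeometryError(f"mask must be 3D, got shape {data.shape}")
        if data.dtype != bool:
            rounded = np.round(data)
            if (
                not np.isin(np.unique(rounded), (0, 1)).all()
                or np.abs(np.asarray(data, dtype=float) - rounded).max() > 1e-6
            ):
                raise GeometryError("mask values must be binary (0/1)")
            data = rounded.astype(bool)
        self.data = data
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive values, got {self.spacing}")
        if len(self.origin) != 3:
            raise GeometryError("origin must have 3 components")

    # -- basic properties -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    def same_grid(self, other: "StructureMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def voxel_coordinates(self) -> np.ndarray:
        """Physical mm coordinates of set-voxel centers, shape (n, 3)."""
        idx = np.argwhere(self.data)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def with_data(self, data: np.ndarray, label: str | None = None) -> "StructureMask":
        return replace(self, data=data, label=label if label is not None else self.label)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box of extreme set-voxel centers, mm.

    ``right >= left``, ``anterior >= posterior``, ``superior >= inferior``
    under the package sign convention.
    """

    right: float
    left: float
    anterior: float
    posterior: float
    superior: float
    inferior: float

    FACES = ("right", "left", "anterior", "posterior", "superior", "inferior")

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.FACES}


def centroid(mask: StructureMask) -> np.ndarray:
    """Unweighted mean of set-voxel center coordinates, in mm (RL, AP, SI)."""
    if mask.is_empty:
        raise EmptyStructureError("cannot compute centroid of an empty mask")
    idx = np.argwhere(mask.data)
    return np.asarray(mask.origin) + idx.mean(axis=0) * np.asarray(mask.spacing)


def bounding_box(mask: StructureMask) -> BoundingBox:
    """Extreme set-voxel-center coordinate per face."""
    if mask.is_empty:
        raise EmptyStructureError("cannot compute bounding box of an empty mask")
    idx = np.argwhere(mask.data)
    lo = np.asarray(mask.origin) + idx.min(axis=0) * np.asarray(mask.spacing)
    hi = np.asarray(mask.origin) + idx.max(axis=0) * np.asarray(mask.spacing)
    return BoundingBox(
        right=float(hi[0]),
        left=float(lo[0]),
        anterior=float(hi[1]),
        posterior=float(lo[1]),
        superior=float(hi[2]),
        inferior=float(lo[2]),
    )


def derive_valve(
    ventricle: StructureMask,
    neighbor: StructureMask,
    expansion_mm: float = 8.0,
    label: str | None = None,
) -> StructureMask:
    """Geometric valve: isotropic expansion of a ventricle intersected with a neighbor.

    The expansion is implemented by thresholding the Euclidean distance
    transform of the ventricle complement at ``expansion_mm`` (spacing-aware,
    sub-voxel accurate), then taking the Boolean intersection with the
    neighboring chamber/vessel.  An empty result (structures further apart
    than the expansion) triggers a warning, not an error.
    """
    if not ventricle.same_grid(neighbor):
        raise GridMismatchError("ventricle and neighbor must share shape/spacing/origin")
    if ventricle.is_empty:
        raise EmptyStructureError("ventricle mask is empty")
    dist = ndimage.distance_transform_edt(~ventricle.data, sampling=ventricle.spacing)
    expanded = dist <= expansion_mm
    valve = expanded & neighbor.data
    if label is None:
        key = (ventricle.label, neighbor.label)
        label = VALVE_PAIRINGS.get(key, "valve")
    if not valve.any():
        warnings.warn(
            f"valve {label}: neighbor lies more than {expansion_mm} mm from the "
            "ventricle; result is empty",
            stacklevel=2,
        )
    return ventricle.with_data(valve, label=label)


def derive_node(
    center_mm: Iterable[float],
    grid_like: StructureMask,
    radius_mm: float = 10.0,
    label: str = "node",
) -> StructureMask:
    """Spherical conduction-node surrogate rasterized on an existing grid.

    The center is an input landmark (placed manually in practice), not
    computed from anatomy.  Voxel-center-inside-sphere rasterization.
    """
    if radius_mm <= 0:
        raise GeometryError(f"node radius must be > 0, got {radius_mm}")
    center = np.asarray(tuple(center_mm), dtype=float)
    sp = np.asarray(grid_like.spacing)
    org = np.asarray(grid_like.origin)
    axes = [org[a] + sp[a] * np.arange(grid_like.shape[a]) for a in range(3)]
    dx = (axes[0] - center[0])[:, None, None]
    dy = (axes[1] - center[1])[None, :, None]
    dz = (axes[2] - center[2])[None, None, :]
    sphere = dx * dx + dy * dy + dz * dz <= radius_mm * radius_mm
    if not sphere.any():
        raise GeometryError("node sphere lies entirely outside the grid")
    return grid_like.with_data(sphere, label=label)


class PhaseGrid:
    """Masks indexed by (substructure, cardiac phase, respiratory state).

    Cardiac phases default to {ED, ES} and respiratory states to
    {EE, AEx, AIn, EI}; both index sets are open (10-phase cardiac grids are
    representable).
    """

    def __init__(self, masks: Mapping[tuple[str, str, str], StructureMask] | None = None):
        self._masks: dict[tuple[str, str, str], StructureMask] = {}
        if masks:
            for key, mask in masks.items():
                self.add(*key, mask)

    def add(self, substructure: str, cardiac: str, resp: str, mask: StructureMask) -> None:
        self._masks[(substructure, cardiac, resp)] = mask

    def get(self, substructure: str, cardiac: str, resp: str) -> StructureMask:
        return self._masks[(substructure, cardiac, resp)]

    def has(self, substructure: str, cardiac: str, resp: str) -> bool:
        return (substructure, cardiac, resp) in self._masks

    def __len__(self) -> int:
        return len(self._masks)

    def __iter__(self):
        return iter(self._masks.items())

    @property
    def substructures(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(k[0] for k in self._masks))

    @property
    def cardiac_phases(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(k[1] for k in self._masks))

    @property
    def resp_states(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(k[2] for k in self._masks))

    def is_complete(
        self,
        substructure: str,
        cardiac_phases: Iterable[str] = CARDIAC_PHASES,
        resp_states: Iterable[str] = RESP_STATES,
    ) -> bool:
        return all(
            self.has(substructure, c, r) for c in cardiac_phases for r in resp_states
        )
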