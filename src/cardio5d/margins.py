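"""Directional internal-margin derivation and IRV construction.

Margins are outward-only: a face moving inward never enlarges the at-risk
envelope (negative outward shifts are floored at 0).  The cardiorespiratory
margin set is the per-face *sum* of the cardiac and respiratory sets (a
Boolean union of the two single-motion IRVs could not represent the combined
worst-case excursion).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientPhasesError, ParameterError
from .structures import BoundingBox, PhaseGrid, StructureMask, bounding_box

FACES = ("right", "left", "anterior", "posterior", "superior", "inferior")

#: (axis, outward sign) per face under the RL/AP/SI convention
_FACE_AXIS_SIGN = {
    "right": (0, +1),
    "left": (0, -1),
    "anterior": (1, +1),
    "posterior": (1, -1),
    "superior": (2, +1),
    "inferior": (2, -1),
}


@dataclass(frozen=True)
class MarginSet:
    """Six outward margins (mm) for one motion type; all non-negative."""

    right: float
    left: float
    anterior: float
    posterior: float
    superior: float
    inferior: float
    motion_type: str = "cardiac"

    def __post_init__(self):
        for f in FACES:
            if getattr(self, f) < 0:
                raise ParameterError(f"margin {f} must be >= 0, got {getattr(self, f)}")

    @property
    def values(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FACES])

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in FACES}

    @classmethod
    def zeros(cls, motion_type: str = "cardiac") -> "MarginSet":
        return cls(0, 0, 0, 0, 0, 0, motion_type=motion_type)

    def __add__(self, other: "MarginSet") -> "MarginSet":
        return MarginSet(
            *(float(a + b) for a, b in zip(self.values, other.values)),
            motion_type="cardiorespiratory",
        )


def _outward_shifts(ref: BoundingBox, target: BoundingBox) -> np.ndarray:
    """Outward shift of each face of ``target`` relative to ``ref`` (mm, signed)."""
    out = np.empty(6)
    for i, f in enumerate(FACES):
        _, sign = _FACE_AXIS_SIGN[f]
        out[i] = sign * (getattr(target, f) - getattr(ref, f))
    return out


def derive_margins(
    grid: PhaseGrid,
    substructure: str,
    motion_type: str,
    cardiac_phases=("ED", "ES"),
    resp_states=("EE", "AEx", "AIn", "EI"),
) -> MarginSet:
    """Per-face internal margin from maximal outward bounding-box shifts.

    cardiac:          max over respiratory states of the outward ED -> ES shift
    respiratory:      max over cardiac phases of the outward shift from EE to
                      every other respiratory state (EI dominates when the
                      stroke is monotone; including AEx/AIn also covers the
                      hysteresis loop)
    cardiorespiratory: per-face sum of the two sets

    Negative (inward) shifts are floored at 0 before the max.
    """
    if motion_type == "cardiorespiratory":
        card = derive_margins(grid, substructure, "cardiac", cardiac_phases, resp_states)
        resp = derive_margins(grid, substructure, "respiratory", cardiac_phases, resp_states)
        return card + resp
    if motion_type == "cardiac":
        pairs = [
            (("ED", r), ("ES", r))
            for r in resp_states
            if grid.has(substructure, "ED", r) and grid.has(substructure, "ES", r)
        ]
    elif motion_type == "respiratory":
        pairs = [
            ((c, "EE"), (c, r))
            for c in cardiac_phases
            for r in resp_states
            if r != "EE"
            and grid.has(substructure, c, "EE")
            and grid.has(substructure, c, r)
        ]
    else:
        raise ParameterError(f"unknown motion type {motion_type!r}")
    if not pairs:
        raise InsufficientPhasesError(
            f"no usable phase pairs for {substructure!r} / {motion_type}"
        )
    shifts = np.zeros(6)
    for (ca, ra), (cb, rb) in pairs:
        ref = bounding_box(grid.get(substructure, ca, ra))
        tgt = bounding_box(grid.get(substructure, cb, rb))
        shifts = np.maximum(shifts, np.maximum(_outward_shifts(ref, tgt), 0.0))
    return MarginSet(*(float(s) for s in shifts), motion_type=motion_type)


def _shift_bool(a: np.ndarray, offset: int, axis: int) -> np.ndarray:
    """Zero-filled shift of a boolean volume by ``offset`` voxels along ``axis``."""
    if offset == 0:
        return a
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if offset > 0:
        dst[axis] = slice(offset, None)
        src[axis] = slice(None, -offset)
    else:
        dst[axis] = slice(None, offset)
        src[axis] = slice(-offset, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _dilate_axis(a: np.ndarray, neg: int, pos: int, axis: int) -> np.ndarray:
    """Minkowski sum with the voxel segment [-neg, +pos] along one axis."""
    out = a.copy()
    for s in range(1, pos + 1):
        out |= _shift_bool(a, s, axis)
    for s in range(1, neg + 1):
        out |= _shift_bool(a, -s, axis)
    return out


def expand_structure(mask: StructureMask, margins: MarginSet) -> StructureMask:
    """IRV: Minkowski sum of the mask with the anisotropic margin box.

    Margins are converted to whole voxels by ceiling (conservative).  The
    expansion is clipped at the grid boundary with a warning if any set voxel
    would leave the array.
    """
    sp = mask.spacing
    vox = {}
    for f in FACES:
        axis, _ = _FACE_AXIS_SIGN[f]
        m = getattr(margins, f)
        vox[f] = int(math.ceil(m / sp[axis] - 1e-9)) if m > 0 else 0
    data = mask.data
    # clipping check: any set voxel within the margin of the array edge?
    idx = np.argwhere(data)
    if idx.size:
        lo = idx.min(axis=0)
        hi = idx.max(axis=0)
        shape = np.asarray(mask.shape)
        neg = np.array([vox["left"], vox["posterior"], vox["inferior"]])
        pos = np.array([vox["right"], vox["anterior"], vox["superior"]])
        if np.any(lo - neg < 0) or np.any(hi + pos > shape - 1):
            warnings.warn(
                "IRV expansion reaches the grid boundary; result is clipped",
                stacklevel=2,
            )
    out = _dilate_axis(data, vox["left"], vox["right"], axis=0)
    out = _dilate_axis(out, vox["posterior"], vox["anterior"], axis=1)
    out = _dilate_axis(out, vox["inferior"], vox["superior"], axis=2)
    label = f"{mask.label}-IRV-{margins.motion_type}" if mask.label else "IRV"
    return mask.with_data(out, label=label)


def derive_irv(
    grid: PhaseGrid,
    substructure: str,
    motion_type: str,
    reference=("ED", "EE"),
    **kwargs,
) -> tuple[StructureMask, MarginSet]:
    """Convenience: derive margins and expand the reference-phase mask."""
    margins = derive_margins(grid, substructure, motion_type, **kwargs)
    ref = grid.get(substructure, reference[0], reference[1])
    return expand_structure(ref, margins), margins
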