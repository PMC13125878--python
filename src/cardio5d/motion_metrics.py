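"""Decoupled cardiac/respiratory/hysteresis excursion metrics.

Cardiac motion: ED -> ES displacement averaged across respiratory states.
Respiratory motion: EE -> EI displacement averaged across cardiac phases.
Hysteresis: AEx -> AIn displacement averaged across cardiac phases.

Averaged vector summaries use the *mean of per-pair vector norms*, not the
norm of the averaged components (mean-of-norms >= norm-of-means).  Averaged
face summaries average each signed face shift across pairs first, then take
mean-abs/max-abs of the averaged faces.

Surface distances are directed (reference A -> target B): for every surface
voxel center of A, the minimum Euclidean distance to B's surface voxel
centers.  Surfaces use 6-connectivity face adjacency; voxels on the array
boundary count as surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree

from .errors import EmptyStructureError, GridMismatchError, InsufficientPhasesError
from .structures import PhaseGrid, StructureMask, bounding_box, centroid

MOTION_TYPES = ("cardiac", "respiratory", "hysteresis")

#: the 8 distance metrics of the cohort statistical analysis
METRICS_8 = ("rl", "ap", "si", "vector", "mean_face", "max_face", "hd95", "mda")


@dataclass(frozen=True)
class Displacement:
    """Signed RL/AP/SI components plus vector magnitude, mm.

    For a single phase pair ``vector`` equals the Euclidean norm of the
    components; for averaged summaries it is the mean of per-pair norms and
    may exceed the norm of the averaged components.
    """

    rl: float
    ap: float
    si: float
    vector: float

    @classmethod
    def from_components(cls, rl: float, ap: float, si: float) -> "Displacement":
        return cls(rl, ap, si, float(np.sqrt(rl * rl + ap * ap + si * si)))

    @classmethod
    def average(cls, items: list["Displacement"]) -> "Displacement":
        if not items:
            raise InsufficientPhasesError("nothing to average")
        return cls(
            rl=float(np.mean([d.rl for d in items])),
            ap=float(np.mean([d.ap for d in items])),
            si=float(np.mean([d.si for d in items])),
            vector=float(np.mean([d.vector for d in items])),
        )

    def __neg__(self) -> "Displacement":
        return Displacement(-self.rl, -self.ap, -self.si, self.vector)


@dataclass(frozen=True)
class FaceDisplacements:
    """Signed bounding-box face shifts (target - reference), mm."""

    right: float
    left: float
    anterior: float
    posterior: float
    superior: float
    inferior: float

    FACES = ("right", "left", "anterior", "posterior", "superior", "inferior")

    @property
    def values(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FACES])

    @property
    def mean_abs(self) -> float:
        return float(np.abs(self.values).mean())

    @property
    def max_abs(self) -> float:
        return float(np.abs(self.values).max())

    @classmethod
    def average(cls, items: list["FaceDisplacements"]) -> "FaceDisplacements":
        if not items:
            raise InsufficientPhasesError("nothing to average")
        mean = np.mean([f.values for f in items], axis=0)
        return cls(*(float(v) for v in mean))


@dataclass(frozen=True)
class DistanceMetrics:
    """Summary of a directed surface-distance sample set, mm."""

    mda: float
    hd95: float
    max: float
    n_points: int


def centroid_displacement(mask_a: StructureMask, mask_b: StructureMask) -> Displacement:
    """Centroid shift B - A in mm (RL, AP, SI) with Euclidean vector norm."""
    _check_pair(mask_a, mask_b)
    d = centroid(mask_b) - centroid(mask_a)
    return Displacement.from_components(float(d[0]), float(d[1]), float(d[2]))


def face_displacements(mask_a: StructureMask, mask_b: StructureMask) -> FaceDisplacements:
    """Signed bounding-box face shifts B - A along each face's axis."""
    _check_pair(mask_a, mask_b)
    ba, bb = bounding_box(mask_a), bounding_box(mask_b)
    return FaceDisplacements(
        right=bb.right - ba.right,
        left=bb.left - ba.left,
        anterior=bb.anterior - ba.anterior,
        posterior=bb.posterior - ba.posterior,
        superior=bb.superior - ba.superior,
        inferior=bb.inferior - ba.inferior,
    )


def _check_pair(a: StructureMask, b: StructureMask) -> None:
    if a.is_empty or b.is_empty:
        raise EmptyStructureError("both masks must be non-empty")
    if not a.same_grid(b):
        raise GridMismatchError("masks must share the same grid frame")


def _averaged_pairs(
    grid: PhaseGrid, substructure: str, pairs: list[tuple[tuple[str, str], tuple[str, str]]]
) -> tuple[Displacement, FaceDisplacements]:
    disps, faces = [], []
    for (ca, ra), (cb, rb) in pairs:
        if grid.has(substructure, ca, ra) and grid.has(substructure, cb, rb):
            a = grid.get(substructure, ca, ra)
            b = grid.get(substructure, cb, rb)
            disps.append(centroid_displacement(a, b))
            faces.append(face_displacements(a, b))
    if not disps:
        raise InsufficientPhasesError(
            f"no complete phase pair for {substructure!r} among {pairs}"
        )
    return Displacement.average(disps), FaceDisplacements.average(faces)


def cardiac_motion(
    grid: PhaseGrid, substructure: str, resp_states=("EE", "AEx", "AIn", "EI")
) -> tuple[Displacement, FaceDisplacements]:
    """ED -> ES displacement averaged across available respiratory states."""
    pairs = [(("ED", r), ("ES", r)) for r in resp_states]
    return _averaged_pairs(grid, substructure, pairs)


def respiratory_motion(
    grid: PhaseGrid, substructure: str, cardiac_phases=("ED", "ES")
) -> tuple[Displacement, FaceDisplacements]:
    """EE -> EI displacement averaged across available cardiac phases."""
    pairs = [((c, "EE"), (c, "EI")) for c in cardiac_phases]
    return _averaged_pairs(grid, substructure, pairs)


def hysteresis(
    grid: PhaseGrid, substructure: str, cardiac_phases=("ED", "ES")
) -> tuple[Displacement, FaceDisplacements]:
    """AEx -> AIn displacement averaged across available cardiac phases.

    A non-zero vector indicates respiratory hysteresis (open inhale/exhale
    loop).
    """
    pairs = [((c, "AEx"), (c, "AIn")) for c in cardiac_phases]
    return _averaged_pairs(grid, substructure, pairs)


def surface_points(mask: StructureMask) -> np.ndarray:
    """Physical mm coordinates of surface voxel centers (6-connectivity)."""
    if mask.is_empty:
        raise EmptyStructureError("cannot extract the surface of an empty mask")
    core = binary_erosion(
        mask.data, structure=generate_binary_structure(3, 1), border_value=0
    )
    idx = np.argwhere(mask.data & ~core)
    return np.asarray(mask.origin) + idx * np.asarray(mask.spacing)


def surface_distances(reference: StructureMask, target: StructureMask) -> np.ndarray:
    """Directed pointwise distance-to-agreement d_a = min_b ||a - b||, mm.

    One distance per surface point of the reference; distances are *not*
    symmetrized.
    """
    pts_a = surface_points(reference)
    pts_b = surface_points(target)
    dists, _ = cKDTree(pts_b).query(pts_a, workers=1)
    return np.asarray(dists, dtype=float)


def distance_metrics(distances: np.ndarray) -> DistanceMetrics:
    """MDA (mean), HD95 (95th percentile, linear interpolation), and max."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise EmptyStructureError("empty distance sample set")
    return DistanceMetrics(
        mda=float(d.mean()),
        hd95=float(np.percentile(d, 95)),
        max=float(d.max()),
        n_points=int(d.size),
    )


# ---------------------------------------------------------------------------
# per-subject motion summaries (long format)
# ---------------------------------------------------------------------------

#: reference/target phase pairs for the voxelwise (MDA/HD95) comparison
_DTA_PAIRS = {
    "cardiac": (("ED", "EE"), ("ES", "EE")),
    "respiratory": (("ED", "EE"), ("ED", "EI")),
}

_MOTION_FUNCS = {
    "cardiac": cardiac_motion,
    "respiratory": respiratory_motion,
    "hysteresis": hysteresis,
}


def summarize_motion(
    grid: PhaseGrid,
    subject: str = "S01",
    substructures=None,
    motion_types=MOTION_TYPES,
) -> pd.DataFrame:
    """Long-format motion metric table for one subject.

    Columns: subject, substructure, motion_type, metric, value_mm.  Metrics
    are rl/ap/si/vector/mean_face/max_face for every motion type, plus
    hd95/mda for cardiac and respiratory motion (the voxelwise comparison is
    defined against the end-exhale end-diastole reference).
    """
    rows = []
    for sub in substructures if substructures is not None else grid.substructures:
        for mt in motion_types:
            disp, faces = _MOTION_FUNCS[mt](grid, sub)
            vals = {
                "rl": disp.rl,
                "ap": disp.ap,
                "si": disp.si,
                "vector": disp.vector,
                "mean_face": faces.mean_abs,
                "max_face": faces.max_abs,
            }
            if mt in _DTA_PAIRS:
                (ca, ra), (cb, rb) = _DTA_PAIRS[mt]
                if grid.has(sub, ca, ra) and grid.has(sub, cb, rb):
                    dm = distance_metrics(
                        surface_distances(grid.get(sub, ca, ra), grid.get(sub, cb, rb))
                    )
                    vals["hd95"] = dm.hd95
                    vals["mda"] = dm.mda
            for metric, value in vals.items():
                rows.append(
                    {
                        "subject": subject,
                        "substructure": sub,
                        "motion_type": mt,
                        "metric": metric,
                        "value_mm": float(value),
                    }
                )
    return pd.DataFrame(rows)


def threshold_flags(summary: pd.DataFrame, threshold_mm: float = 5.0) -> pd.DataFrame:
    """Per-subject >threshold flags for centroid-vector and max-face motion.

    The comparison is strict (>), so exactly-at-threshold motion is not
    flagged.  Returns one row per (subject, substructure, motion_type) with
    boolean ``centroid_exceeds`` / ``face_exceeds``.
    """
    wide = summary.pivot_table(
        index=["subject", "substructure", "motion_type"],
        columns="metric",
        values="value_mm",
        aggfunc="first",
    ).reset_index()
    wide["centroid_exceeds"] = wide["vector"] > threshold_mm
    wide["face_exceeds"] = wide["max_face"] > threshold_mm
    return wide[
        ["subject", "substructure", "motion_type", "vector", "max_face",
         "centroid_exceeds", "face_exceeds"]
    ]


def exceed_counts(summary: pd.DataFrame, threshold_mm: float = 5.0) -> pd.DataFrame:
    """Cohort count table of subjects exceeding the motion threshold.

    Rows: (measure in {centroid, bounding_box}) x motion_type; columns:
    substructures; values: number of subjects with motion > threshold.
    """
    flags = threshold_flags(summary, threshold_mm)
    out = []
    for measure, col in (("centroid", "centroid_exceeds"), ("bounding_box", "face_exceeds")):
        counts = (
            flags.groupby(["motion_type", "substructure"], observed=True)[col]
            .sum()
            .astype(int)
            .unstack("substructure")
        )
        counts.insert(0, "measure", measure)
        out.append(counts.reset_index())
    return pd.concat(out, ignore_index=True)
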