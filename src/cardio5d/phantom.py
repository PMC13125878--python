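"""Synthetic phantom: surrogate signals, moving substructure masks, dose grids.

Every downstream stage (binning, motion metrics, margins, dosimetry, stats) is
testable against this module's *known ground truth*: the exact displacement
applied to each primitive at each (cardiac phase, respiratory state) is
recorded alongside the rendered masks.

Motion model
------------
The displacement of a substructure at cardiac phase fraction ``f`` (0 = ED,
1 = ES) and respiratory phase fraction ``p`` (0 = EE, 1 = EI) on limb
``l`` (+1 inhale, -1 exhale) is::

    d(f, p, l) = cardiac_amp * s(f) + resp_amp * s(p)
                 + l * (hysteresis_mm / 2) * sin(pi * p) * u_perp

with ``s`` a raised cosine (``s(0)=0``, ``s(1)=1``) and ``u_perp`` a unit
vector perpendicular to the respiratory stroke.  The sine factor closes the
loop at both respiratory extremes; the inhale and exhale limbs are separated
by exactly ``hysteresis_mm`` at mid-respiration (AEx vs AIn).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError
from .structures import PhaseGrid, StructureMask

__all__ = [
    "Sphere",
    "Tube",
    "Ellipsoid",
    "PhantomSpec",
    "MotionModel",
    "RespiratoryWaveform",
    "CardiacTriggers",
    "DoseGridSpec",
    "generate_respiratory_waveform",
    "generate_cardiac_triggers",
    "render_mask",
    "render_phase_grid",
    "render_dose",
    "default_phantom_spec",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]  # mm
    radius: float  # mm

    def __post_init__(self):
        if self.radius <= 0:
            raise GeometryError(f"sphere radius must be > 0, got {self.radius}")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, dtype=float)
        return c - self.radius, c + self.radius

    def contains(self, x, y, z, displacement):
        cx, cy, cz = np.asarray(self.center) + displacement
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius**2


@dataclass(frozen=True)
class Tube:
    """Capsule around an axis polyline (vessel surrogate)."""

    points: tuple[tuple[float, float, float], ...]  # polyline vertices, mm
    radius: float  # mm

    def __post_init__(self):
        if self.radius <= 0:
            raise GeometryError(f"tube radius must be > 0, got {self.radius}")
        if len(self.points) < 2:
            raise GeometryError("tube polyline needs at least 2 points")

    def bounds(self):
        pts = np.asarray(self.points, dtype=float)
        return pts.min(axis=0) - self.radius, pts.max(axis=0) + self.radius

    def contains(self, x, y, z, displacement):
        pts = np.asarray(self.points, dtype=float) + displacement
        inside = np.zeros(np.broadcast(x, y, z).shape, dtype=bool)
        r2 = self.radius**2
        for a, b in zip(pts[:-1], pts[1:]):
            ab = b - a
            denom = float(ab @ ab)
            px, py, pz = x - a[0], y - a[1], z - a[2]
            if denom == 0.0:
                d2 = px * px + py * py + pz * pz
            else:
                t = np.clip((px * ab[0] + py * ab[1] + pz * ab[2]) / denom, 0.0, 1.0)
                d2 = (px - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (pz - t * ab[2]) ** 2
            inside |= d2 <= r2
        return inside


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]  # mm
    semi_axes: tuple[float, float, float]  # mm

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise GeometryError(f"ellipsoid semi-axes must be > 0, got {self.semi_axes}")

    def bounds(self):
        c = np.asarray(self.center, dtype=float)
        s = np.asarray(self.semi_axes, dtype=float)
        return c - s, c + s

    def contains(self, x, y, z, displacement):
        cx, cy, cz = np.asarray(self.center) + displacement
        ax, ay, az = self.semi_axes
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


Primitive = Sphere | Tube | Ellipsoid


@dataclass
class PhantomSpec:
    """Grid geometry plus the geometric primitive of each substructure."""

    substructures: dict[str, Primitive]
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.56, 1.56, 1.56)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.grid_shape):
            raise GeometryError(f"grid shape must be positive, got {self.grid_shape}")

    def axes_mm(self) -> list[np.ndarray]:
        org = np.asarray(self.origin)
        sp = np.asarray(self.spacing)
        return [org[a] + sp[a] * np.arange(self.grid_shape[a]) for a in range(3)]

    def extent_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical grid extent including the outer half-voxel shell."""
        org = np.asarray(self.origin)
        sp = np.asarray(self.spacing)
        n = np.asarray(self.grid_shape)
        return org - sp / 2, org + sp * (n - 1) + sp / 2


# ---------------------------------------------------------------------------
# motion model
# ---------------------------------------------------------------------------

def _raised_cosine(f: float) -> float:
    return 0.5 * (1.0 - math.cos(math.pi * f))


#: cardiac phase name -> phase fraction (0 = ED, 1 = ES)
CARDIAC_FRACTION = {"ED": 0.0, "ES": 1.0}

#: respiratory state -> (phase fraction 0=EE..1=EI, limb sign: +1 inhale, -1 exhale)
RESP_PHASE = {"EE": (0.0, 0), "AEx": (0.5, -1), "AIn": (0.5, +1), "EI": (1.0, 0)}


@dataclass
class MotionModel:
    """Prescribed substructure displacement over the cardiorespiratory cycle.

    Components are (RL, AP, SI) mm with the package sign convention.
    ``hysteresis_mm`` is the perpendicular separation between the inhale and
    exhale limbs at mid-respiration; the loop closes exactly at EE and EI.
    """

    cardiac_amp: tuple[float, float, float] = (0.0, 0.0, 0.0)  # ED -> ES
    resp_amp: tuple[float, float, float] = (0.0, 0.0, 0.0)  # EE -> EI
    hysteresis_mm: float = 0.0
    hysteresis_axis: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.hysteresis_mm < 0:
            raise ParameterError("hysteresis_mm must be >= 0")

    def perp_axis(self) -> np.ndarray:
        if self.hysteresis_axis is not None:
            v = np.asarray(self.hysteresis_axis, dtype=float)
            n = np.linalg.norm(v)
            if n == 0:
                raise ParameterError("hysteresis_axis must be non-zero")
            return v / n
        resp = np.asarray(self.resp_amp, dtype=float)
        if np.linalg.norm(resp) == 0:
            return np.array([1.0, 0.0, 0.0])
        v = np.cross(resp, [0.0, 0.0, 1.0])
        if np.linalg.norm(v) < 1e-12:  # SI-only stroke
            v = np.cross(resp, [1.0, 0.0, 0.0])
        return v / np.linalg.norm(v)

    def displacement(self, cardiac_phase: str, resp_state: str) -> np.ndarray:
        """Exact displacement (mm) at one (cardiac phase, respiratory state)."""
        try:
            f = CARDIAC_FRACTION[cardiac_phase]
        except KeyError:
            raise ParameterError(f"unknown cardiac phase {cardiac_phase!r}") from None
        try:
            p, limb = RESP_PHASE[resp_state]
        except KeyError:
            raise ParameterError(f"unknown respiratory state {resp_state!r}") from None
        d = np.asarray(self.cardiac_amp, dtype=float) * _raised_cosine(f)
        d = d + np.asarray(self.resp_amp, dtype=float) * _raised_cosine(p)
        if limb and self.hysteresis_mm:
            d = d + limb * (self.hysteresis_mm / 2.0) * math.sin(math.pi * p) * self.perp_axis()
        return d

    def max_abs_displacement(self) -> np.ndarray:
        """Loose per-axis bound on |displacement| over all phases."""
        return (
            np.abs(self.cardiac_amp)
            + np.abs(self.resp_amp)
            + (self.hysteresis_mm / 2.0) * np.abs(self.perp_axis())
        )


# ---------------------------------------------------------------------------
# surrogate signals
# ---------------------------------------------------------------------------

@dataclass
class RespiratoryWaveform:
    times: np.ndarray  # s, uniform step
    amplitudes: np.ndarray  # a.u.
    period: float  # s
    drift_rate: float = 0.0
    noise_sd: float = 0.0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "amplitude": self.amplitudes})


@dataclass
class CardiacTriggers:
    trigger_times: np.ndarray  # s, strictly increasing
    mean_rr: float
    rr_jitter_sd: float = 0.0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"trigger_time_s": self.trigger_times})


def generate_respiratory_waveform(
    duration_s: float,
    dt_s: float = 0.02,
    period_s: float = 4.0,
    amplitude: float = 1.0,
    midline: float = 0.0,
    drift_rate: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> RespiratoryWaveform:
    """Quasi-periodic bellows-style waveform.

    Shape is ``midline - amplitude*cos(2*pi*t/period)`` (end-exhale trough at
    t=0, end-inhale peak mid-period), plus linear baseline drift and i.i.d.
    Gaussian noise.  With ``noise_sd=0`` and ``drift_rate=0`` the signal is
    exactly periodic with the stated period.
    """
    if period_s <= 0:
        raise ParameterError(f"period must be > 0, got {period_s}")
    if dt_s <= 0:
        raise ParameterError(f"sampling step must be > 0, got {dt_s}")
    if dt_s >= period_s / 10:
        raise ParameterError(
            f"sampling step {dt_s} too coarse for period {period_s} (need < period/10)"
        )
    if duration_s <= 0:
        raise ParameterError("duration must be > 0")
    n = int(math.floor(duration_s / dt_s)) + 1
    t = np.arange(n) * dt_s
    amp = midline - amplitude * np.cos(2 * np.pi * t / period_s) + drift_rate * t
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        amp = amp + rng.normal(0.0, noise_sd, size=n)
    return RespiratoryWaveform(
        times=t, amplitudes=amp, period=period_s,
        drift_rate=drift_rate, noise_sd=noise_sd, seed=seed,
    )


def generate_cardiac_triggers(
    duration_s: float,
    mean_rr_s: float = 1.0,
    rr_jitter_sd_s: float = 0.0,
    seed: int | None = None,
) -> CardiacTriggers:
    """Pulse-oximeter-style trigger train covering [0, duration]."""
    if mean_rr_s <= 0:
        raise ParameterError(f"mean RR must be > 0, got {mean_rr_s}")
    if duration_s <= mean_rr_s:
        raise ParameterError("duration must exceed the mean RR interval")
    rng = np.random.default_rng(seed)
    times = [0.0]
    while times[-1] < duration_s:
        rr = mean_rr_s
        if rr_jitter_sd_s > 0:
            rr = mean_rr_s + rng.normal(0.0, rr_jitter_sd_s)
        if rr <= 0:
            raise ParameterError(
                "RR jitter produced a non-positive interval; reduce rr_jitter_sd"
            )
        times.append(times[-1] + rr)
    return CardiacTriggers(
        trigger_times=np.asarray(times), mean_rr=mean_rr_s,
        rr_jitter_sd=rr_jitter_sd_s, seed=seed,
    )


# ---------------------------------------------------------------------------
# mask / phase-grid rendering
# ---------------------------------------------------------------------------

def render_mask(
    spec: PhantomSpec,
    substructure: str,
    displacement=(0.0, 0.0, 0.0),
) -> StructureMask:
    """Rasterize one displaced primitive (voxel-center-inside rule)."""
    try:
        prim = spec.substructures[substructure]
    except KeyError:
        raise ParameterError(f"unknown substructure {substructure!r}") from None
    disp = np.asarray(displacement, dtype=float)
    lo, hi = prim.bounds()
    ext_lo, ext_hi = spec.extent_mm()
    if np.any(lo + disp < ext_lo) or np.any(hi + disp > ext_hi):
        raise GeometryError(
            f"displaced primitive {substructure!r} extends outside the grid "
            f"(bounds {lo + disp}..{hi + disp}, grid {ext_lo}..{ext_hi})"
        )
    ax, ay, az = spec.axes_mm()
    inside = prim.contains(
        ax[:, None, None], ay[None, :, None], az[None, None, :], disp
    )
    if not inside.any():
        raise GeometryError(f"primitive {substructure!r} rasterized to an empty mask")
    return StructureMask(inside, spec.spacing, spec.origin, label=substructure)


def render_phase_grid(
    spec: PhantomSpec,
    models: MotionModel | dict[str, MotionModel],
    cardiac_phases=("ED", "ES"),
    resp_states=("EE", "AEx", "AIn", "EI"),
) -> tuple[PhaseGrid, pd.DataFrame]:
    """Render all (substructure, cardiac, respiratory) masks plus ground truth.

    ``models`` is either one model applied to every substructure or a mapping
    substructure -> model.  The returned table records the exact displacement
    applied per (substructure, cardiac phase, respiratory state).
    """
    grid = PhaseGrid()
    rows = []
    for name in spec.substructures:
        model = models[name] if isinstance(models, dict) else models
        for c in cardiac_phases:
            for r in resp_states:
                d = model.displacement(c, r)
                grid.add(name, c, r, render_mask(spec, name, d))
                rows.append(
                    {
                        "substructure": name,
                        "cardiac_phase": c,
                        "resp_state": r,
                        "rl_mm": d[0],
                        "ap_mm": d[1],
                        "si_mm": d[2],
                    }
                )
    return grid, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dose grids
# ---------------------------------------------------------------------------

@dataclass
class DoseGridSpec:
    """Synthetic dose field on a phantom-style grid (stands in for a TPS plan)."""

    mode: str = "uniform"  # uniform | linear_gradient | gaussian
    level_gy: float = 10.0
    gradient_gy_per_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gradient_ref_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    peak_gy: float = 60.0
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    width_mm: float = 20.0
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.56, 1.56, 1.56)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


def render_dose(spec: DoseGridSpec):
    """Deterministic synthetic dose grid; dose >= 0 everywhere by construction."""
    from .dosimetry import DoseGrid  # local import avoids a module cycle

    org = np.asarray(spec.origin)
    sp = np.asarray(spec.spacing)
    axes = [org[a] + sp[a] * np.arange(spec.grid_shape[a]) for a in range(3)]
    if spec.mode == "uniform":
        if spec.level_gy < 0:
            raise ParameterError("uniform dose level must be >= 0")
        values = np.full(spec.grid_shape, float(spec.level_gy))
    elif spec.mode == "linear_gradient":
        if spec.level_gy < 0:
            raise ParameterError("gradient base level must be >= 0")
        g = np.asarray(spec.gradient_gy_per_mm, dtype=float)
        x0 = np.asarray(spec.gradient_ref_mm, dtype=float)
        values = (
            spec.level_gy
            + g[0] * (axes[0] - x0[0])[:, None, None]
            + g[1] * (axes[1] - x0[1])[None, :, None]
            + g[2] * (axes[2] - x0[2])[None, None, :]
        )
        values = np.clip(values, 0.0, None)
    elif spec.mode == "gaussian":
        if spec.peak_gy < 0:
            raise ParameterError("gaussian peak must be >= 0")
        if spec.width_mm <= 0:
            raise ParameterError("gaussian width must be > 0")
        c = np.asarray(spec.center_mm, dtype=float)
        r2 = (
            (axes[0] - c[0])[:, None, None] ** 2
            + (axes[1] - c[1])[None, :, None] ** 2
            + (axes[2] - c[2])[None, None, :] ** 2
        )
        values = spec.peak_gy * np.exp(-r2 / (2.0 * spec.width_mm**2))
    else:
        raise ParameterError(f"unknown dose mode {spec.mode!r}")
    return DoseGrid(values, spec.spacing, spec.origin)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def default_phantom_spec(
    grid_shape=(96, 96, 96), spacing=(1.56, 1.56, 1.56)
) -> PhantomSpec:
    """Two-substructure desk phantom: a vessel-like tube and a chamber-like sphere.

    Primitives are centered so that displacements up to ~10 mm per axis stay
    inside the grid.
    """
    extent = np.asarray(grid_shape) * np.asarray(spacing)
    c = extent / 2.0
    # geometry drawn for a ~150 mm field of view, scaled to smaller grids
    k = min(1.0, float(extent.min()) / 150.0)
    tube = Tube(
        points=(
            (c[0] + 25.0 * k, c[1], c[2] + 25.0 * k),
            (c[0] + 28.0 * k, c[1] + 6.0 * k, c[2]),
            (c[0] + 25.0 * k, c[1], c[2] - 25.0 * k),
        ),
        radius=max(5.0 * k, 2.0 * float(np.max(spacing))),
    )
    sphere = Sphere(center=(c[0] - 12.0 * k, c[1], c[2]), radius=24.0 * k)
    return PhantomSpec(
        substructures={"RCA": tube, "LV": sphere},
        grid_shape=tuple(grid_shape),
        spacing=tuple(spacing),
    )


def simulate_cohort(
    n_subjects: int,
    spec: PhantomSpec | None = None,
    base_models: dict[str, MotionModel] | None = None,
    amp_jitter_sd_mm: float = 0.0,
    seed: int | None = None,
    cardiac_phases=("ED", "ES"),
    resp_states=("EE", "AEx", "AIn", "EI"),
) -> list[tuple[str, PhaseGrid, pd.DataFrame]]:
    """Simulate a cohort of phantom subjects with known per-subject motion.

    Each subject's amplitudes are the base model's plus optional Gaussian
    inter-subject jitter (componentwise, also applied to the hysteresis
    magnitude, floored at 0).  Returns ``(subject_id, phase_grid, truth)``
    triples; the truth table carries the exact per-phase displacements.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    spec = spec if spec is not None else default_phantom_spec()
    if base_models is None:
        base_models = {
            name: MotionModel(
                cardiac_amp=(-5.5, 3.8, -3.6),
                resp_amp=(0.0, 1.0, -4.0),
                hysteresis_mm=2.0,
            )
            for name in spec.substructures
        }
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        models = {}
        for name, base in base_models.items():
            if amp_jitter_sd_mm > 0:
                card = np.asarray(base.cardiac_amp) + rng.normal(0, amp_jitter_sd_mm, 3)
                resp = np.asarray(base.resp_amp) + rng.normal(0, amp_jitter_sd_mm, 3)
                hyst = max(0.0, base.hysteresis_mm + rng.normal(0, amp_jitter_sd_mm))
            else:
                card, resp, hyst = base.cardiac_amp, base.resp_amp, base.hysteresis_mm
            models[name] = MotionModel(
                cardiac_amp=tuple(card),
                resp_amp=tuple(resp),
                hysteresis_mm=hyst,
                hysteresis_axis=base.hysteresis_axis,
            )
        grid, truth = render_phase_grid(spec, models, cardiac_phases, resp_states)
        subject = f"S{i + 1:02d}"
        truth.insert(0, "subject", subject)
        cohort.append((subject, grid, truth))
    return cohort
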