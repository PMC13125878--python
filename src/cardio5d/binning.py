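"""Retrospective cardiac/respiratory bin assignment from surrogate signals.

Cardiac binning is phase-based: within each RR interval the phase fraction is
split into ``n_bins`` equal bins.  Respiratory binning is amplitude-based with
a 10%/80%/10% split: samples in the top decile of the (baseline-corrected)
waveform are end-inhale (EI), the bottom decile end-exhale (EE), and the
middle 80% is split into active inhale (AIn) / active exhale (AEx) by the
local slope sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import DegenerateSignalError, ParameterError

RESP_STATES = ("EE", "AEx", "AIn", "EI")

UNASSIGNED = -1


@dataclass
class BinAssignment:
    """Per-sample (cardiac bin, respiratory state) assignment.

    ``cardiac_bin`` is ``UNASSIGNED`` (-1) for samples outside the trigger
    range; those samples are excluded from occupancy summaries.
    """

    times: np.ndarray
    cardiac_bin: np.ndarray  # int, -1 = unassigned
    resp_state: np.ndarray  # str
    n_cardiac_bins: int
    amplitude_thresholds: tuple[float, float]  # (lower, upper) on corrected signal
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "cardiac_bin": self.cardiac_bin,
                "resp_state": self.resp_state,
            }
        )


def assign_cardiac_phase(
    times: np.ndarray, trigger_times: np.ndarray, n_bins: int = 10
) -> tuple[np.ndarray, int]:
    """Phase-based cardiac bin per sample.

    bin = floor(n_bins * (t - t_k) / (t_{k+1} - t_k)) for the RR interval
    enclosing t, clamped to n_bins - 1.  Samples outside [first, last]
    trigger are returned as UNASSIGNED and counted.
    """
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    trig = np.asarray(trigger_times, dtype=float)
    if trig.ndim != 1 or trig.size < 2:
        raise ParameterError("need at least two trigger times")
    if np.any(np.diff(trig) <= 0):
        raise ParameterError("trigger times must be strictly increasing")
    t = np.asarray(times, dtype=float)
    bins = np.full(t.shape, UNASSIGNED, dtype=int)
    inside = (t >= trig[0]) & (t <= trig[-1])
    k = np.clip(np.searchsorted(trig, t[inside], side="right") - 1, 0, trig.size - 2)
    frac = (t[inside] - trig[k]) / (trig[k + 1] - trig[k])
    # epsilon guards samples that fall exactly on a bin boundary against
    # floating-point rounding below it
    b = np.clip(np.floor(n_bins * frac + 1e-9).astype(int), 0, n_bins - 1)
    # a sample exactly on the final trigger has phase fraction 0, not 1
    b[t[inside] == trig[-1]] = 0
    bins[inside] = b
    return bins, int((~inside).sum())


def correct_baseline(
    amplitudes: np.ndarray, times: np.ndarray, window_s: float
) -> np.ndarray:
    """Subtract a moving-average baseline (window in seconds, nearest-edge padded)."""
    if window_s <= 0:
        raise ParameterError("baseline window must be > 0")
    t = np.asarray(times, dtype=float)
    dt = float(t[1] - t[0])
    size = max(1, int(round(window_s / dt)))
    size += 1 - size % 2  # odd window -> symmetric filter (no half-sample lag)
    baseline = uniform_filter1d(np.asarray(amplitudes, dtype=float), size, mode="nearest")
    return np.asarray(amplitudes, dtype=float) - baseline


def assign_respiratory_state(
    times: np.ndarray,
    amplitudes: np.ndarray,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
    baseline_window_s: float | None = None,
    slope_window_s: float = 0.5,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Amplitude-based 10/80/10 respiratory state per sample.

    Thresholds are sample percentiles of the (optionally baseline-corrected)
    waveform.  The middle band is split by the sign of the local slope of a
    moving-average-smoothed copy (central differences); exact zero slope
    tie-breaks to AEx.  Returns (states, (lower, upper) thresholds).
    """
    t = np.asarray(times, dtype=float)
    amp = np.asarray(amplitudes, dtype=float)
    if t.size != amp.size or t.size < 3:
        raise ParameterError("times/amplitudes must be equal length >= 3")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ParameterError("times must be strictly increasing with uniform step")
    if not 0 < lower_pct < upper_pct < 100:
        raise ParameterError("need 0 < lower_pct < upper_pct < 100")
    if baseline_window_s is not None:
        amp = correct_baseline(amp, t, baseline_window_s)
    lo, hi = np.percentile(amp, [lower_pct, upper_pct])
    if hi - lo < 1e-12:
        raise DegenerateSignalError(
            "amplitude percentiles coincide (constant waveform?); cannot bin"
        )
    size = max(1, int(round(slope_window_s / float(dt[0]))))
    smooth = uniform_filter1d(amp, size, mode="nearest")
    slope = np.gradient(smooth, t)
    states = np.where(slope > 0, "AIn", "AEx").astype(object)
    states[amp >= hi] = "EI"
    states[amp <= lo] = "EE"
    return np.asarray(states, dtype="U3"), (float(lo), float(hi))


def assign_bins(
    times: np.ndarray,
    amplitudes: np.ndarray,
    trigger_times: np.ndarray,
    n_cardiac_bins: int = 10,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
    baseline_window_s: float | None = None,
    slope_window_s: float = 0.5,
) -> BinAssignment:
    """Joint cardiac-phase and respiratory-state assignment for a record."""
    cardiac, n_excluded = assign_cardiac_phase(times, trigger_times, n_cardiac_bins)
    resp, thresholds = assign_respiratory_state(
        times,
        amplitudes,
        lower_pct=lower_pct,
        upper_pct=upper_pct,
        baseline_window_s=baseline_window_s,
        slope_window_s=slope_window_s,
    )
    return BinAssignment(
        times=np.asarray(times, dtype=float),
        cardiac_bin=cardiac,
        resp_state=resp,
        n_cardiac_bins=n_cardiac_bins,
        amplitude_thresholds=thresholds,
        n_excluded=n_excluded,
    )


def summarize_bins(assignment: BinAssignment) -> pd.DataFrame:
    """Occupancy table over assigned samples.

    Long format: (cardiac_bin, resp_state, count, fraction); fractions sum to
    1 over assigned samples.
    """
    mask = assignment.cardiac_bin != UNASSIGNED
    if not mask.any():
        raise ParameterError("no assigned samples to summarize")
    df = pd.DataFrame(
        {
            "cardiac_bin": assignment.cardiac_bin[mask],
            "resp_state": assignment.resp_state[mask],
        }
    )
    counts = (
        df.groupby(["cardiac_bin", "resp_state"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    counts["fraction"] = counts["count"] / counts["count"].sum()
    return counts


def state_fractions(assignment: BinAssignment) -> dict[str, float]:
    """Fraction of assigned samples per respiratory state (absent states -> 0)."""
    summary = summarize_bins(assignment)
    by_state = summary.groupby("resp_state", observed=True)["fraction"].sum()
    return {s: float(by_state.get(s, 0.0)) for s in RESP_STATES}
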