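"""Configuration-driven orchestration of the end-to-end phantom study.

Stages (each runnable alone or chained by :func:`run_full`):

simulate  -> per-subject phase-grid masks (NIfTI), surrogate signals,
             triggers, ground-truth displacement table, synthetic dose grid
bin       -> cardiac/respiratory bin assignment from the surrogate signals
motion    -> long-format motion metric table + >5 mm count table
margins   -> per-subject/per-substructure margin table + IRV masks
dose      -> DVH and D_0.03cc / ΔD_0.03cc tables for reference vs IRV
stats     -> grouping comparison tables + significance summary matrix

Every run writes its resolved configuration (including the seed) next to its
outputs; with a fixed seed all CSV outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binning, io, motion_metrics, phantom, stats
from .dosimetry import structure_d_cc
from .errors import ParameterError
from .margins import FACES, derive_irv
from .structures import PhaseGrid

log = logging.getLogger("cardio5d")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_subjects": 3,
    "grid_shape": [64, 64, 64],
    "spacing": [1.56, 1.56, 1.56],
    "cardiac_amp": [-5.5, 3.8, -3.6],
    "resp_amp": [0.0, 1.0, -4.0],
    "hysteresis_mm": 2.0,
    "amp_jitter_sd_mm": 0.5,
    "signals": {
        "duration_s": 300.0,
        "dt_s": 0.02,
        "resp_period_s": 4.0,
        "resp_noise_sd": 0.02,
        "drift_rate": 0.0,
        "mean_rr_s": 1.0,
        "rr_jitter_sd_s": 0.03,
    },
    "binning": {"n_cardiac": 10, "lower_pct": 10.0, "upper_pct": 90.0,
                "slope_window_s": 0.5},
    "threshold_mm": 5.0,
    "v_cc": 0.03,
    "dose": {
        "mode": "linear_gradient",
        "level_gy": 30.0,
        "gradient_gy_per_mm": [0.0, 0.0, 0.5],
        "gradient_ref_mm": [50.0, 50.0, 50.0],
    },
    "stats": {"alpha": 0.05, "min_significant": 4},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (v.copy() if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, overrides)


def _write_resolved_config(cfg: dict, outdir: Path, stage: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"config_{stage}.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _phantom_spec(cfg: dict) -> phantom.PhantomSpec:
    return phantom.default_phantom_spec(
        grid_shape=tuple(cfg["grid_shape"]), spacing=tuple(cfg["spacing"])
    )


def run_simulate(cfg: dict, outdir) -> Path:
    """Write the full synthetic cohort: masks, signals, triggers, truth, dose."""
    outdir = Path(outdir)
    t0 = time.time()
    _write_resolved_config(cfg, outdir, "simulate")
    spec = _phantom_spec(cfg)
    base = {
        name: phantom.MotionModel(
            cardiac_amp=tuple(cfg["cardiac_amp"]),
            resp_amp=tuple(cfg["resp_amp"]),
            hysteresis_mm=float(cfg["hysteresis_mm"]),
        )
        for name in spec.substructures
    }
    cohort = phantom.simulate_cohort(
        cfg["n_subjects"],
        spec=spec,
        base_models=base,
        amp_jitter_sd_mm=float(cfg["amp_jitter_sd_mm"]),
        seed=cfg["seed"],
    )
    sig = cfg["signals"]
    manifest_rows = []
    truths = []
    for i, (subject, grid, truth) in enumerate(cohort):
        sdir = outdir / subject
        wave = phantom.generate_respiratory_waveform(
            duration_s=sig["duration_s"],
            dt_s=sig["dt_s"],
            period_s=sig["resp_period_s"],
            noise_sd=sig["resp_noise_sd"],
            drift_rate=sig["drift_rate"],
            seed=cfg["seed"] * 10_000 + 2 * i,
        )
        trig = phantom.generate_cardiac_triggers(
            duration_s=sig["duration_s"],
            mean_rr_s=sig["mean_rr_s"],
            rr_jitter_sd_s=sig["rr_jitter_sd_s"],
            seed=cfg["seed"] * 10_000 + 2 * i + 1,
        )
        io.write_signal(wave.times, wave.amplitudes, sdir / "resp.csv")
        io.write_triggers(trig.trigger_times, sdir / "triggers.csv")
        for (sub, c, r), mask in grid:
            fname = io.mask_filename(sub, c, r)
            io.write_mask(mask, sdir / "masks" / fname)
            manifest_rows.append(
                {
                    "subject": subject,
                    "substructure": sub,
                    "cardiac_phase": c,
                    "resp_state": r,
                    "file": f"{subject}/masks/{fname}",
                }
            )
        truths.append(truth)
    io.write_table(pd.concat(truths, ignore_index=True), outdir / "ground_truth_mm.csv")
    io.write_table(pd.DataFrame(manifest_rows), outdir / "manifest.csv")
    dose_cfg = cfg["dose"]
    dose = phantom.render_dose(
        phantom.DoseGridSpec(
            mode=dose_cfg["mode"],
            level_gy=float(dose_cfg.get("level_gy", 10.0)),
            gradient_gy_per_mm=tuple(dose_cfg.get("gradient_gy_per_mm", (0, 0, 0))),
            gradient_ref_mm=tuple(dose_cfg.get("gradient_ref_mm", (0, 0, 0))),
            peak_gy=float(dose_cfg.get("peak_gy", 60.0)),
            center_mm=tuple(dose_cfg.get("center_mm", (0, 0, 0))),
            width_mm=float(dose_cfg.get("width_mm", 20.0)),
            grid_shape=tuple(cfg["grid_shape"]),
            spacing=tuple(cfg["spacing"]),
        )
    )
    io.write_dose(dose, outdir / "dose.nii")
    log.info("simulate: %d subjects in %.1f s", len(cohort), time.time() - t0)
    return outdir


def load_cohort(outdir) -> list[tuple[str, PhaseGrid]]:
    """Rebuild per-subject phase grids from a simulate output directory."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    cohort = []
    for subject, rows in manifest.groupby("subject", observed=True):
        grid = PhaseGrid()
        for _, row in rows.iterrows():
            mask = io.read_mask(outdir / row["file"], label=row["substructure"])
            grid.add(row["substructure"], row["cardiac_phase"], row["resp_state"], mask)
        cohort.append((subject, grid))
    return cohort


def run_bin(cfg: dict, simdir, outdir) -> Path:
    """Assign cardiac/respiratory bins for every subject's surrogate signals."""
    simdir, outdir = Path(simdir), Path(outdir)
    _write_resolved_config(cfg, outdir, "bin")
    bcfg = cfg["binning"]
    occupancy = []
    for sdir in sorted(p for p in simdir.iterdir() if (p / "resp.csv").exists()):
        times, amp = io.read_signal(sdir / "resp.csv")
        trig = io.read_triggers(sdir / "triggers.csv")
        assignment = binning.assign_bins(
            times,
            amp,
            trig,
            n_cardiac_bins=int(bcfg["n_cardiac"]),
            lower_pct=float(bcfg["lower_pct"]),
            upper_pct=float(bcfg["upper_pct"]),
            baseline_window_s=2.0 * float(cfg["signals"]["resp_period_s"]),
            slope_window_s=float(bcfg["slope_window_s"]),
        )
        io.write_table(assignment.to_frame(), outdir / f"{sdir.name}_assignment.csv")
        summary = binning.summarize_bins(assignment)
        summary.insert(0, "subject", sdir.name)
        occupancy.append(summary)
    if not occupancy:
        raise ParameterError(f"no subject signals found under {simdir}")
    io.write_table(pd.concat(occupancy, ignore_index=True), outdir / "occupancy.csv")
    return outdir


def run_motion(cfg: dict, simdir, outdir) -> Path:
    """Motion metric table and >threshold count table for the cohort."""
    outdir = Path(outdir)
    _write_resolved_config(cfg, outdir, "motion")
    frames = [
        motion_metrics.summarize_motion(grid, subject=subject)
        for subject, grid in load_cohort(simdir)
    ]
    table = pd.concat(frames, ignore_index=True)
    io.write_table(table, outdir / "motion_metrics_mm.csv")
    counts = motion_metrics.exceed_counts(table, threshold_mm=float(cfg["threshold_mm"]))
    io.write_table(counts, outdir / "exceed_counts.csv")
    return outdir


def run_margins(cfg: dict, simdir, outdir) -> Path:
    """Directional margins and IRV masks per subject/substructure/motion type."""
    outdir = Path(outdir)
    _write_resolved_config(cfg, outdir, "margins")
    rows = []
    for subject, grid in load_cohort(simdir):
        for sub in grid.substructures:
            for mt in ("cardiac", "respiratory", "cardiorespiratory"):
                irv, margins = derive_irv(grid, sub, mt)
                io.write_mask(irv, outdir / subject / f"irv_{sub}_{mt}.nii")
                row = {"subject": subject, "substructure": sub, "motion_type": mt}
                row.update({f"{f}_mm": getattr(margins, f) for f in FACES})
                rows.append(row)
    io.write_table(pd.DataFrame(rows), outdir / "margins_mm.csv")
    return outdir


def run_dose(cfg: dict, simdir, margindir, outdir) -> Path:
    """D_0.03cc for reference and IRV structures plus ΔD on the synthetic plan."""
    simdir, margindir, outdir = Path(simdir), Path(margindir), Path(outdir)
    _write_resolved_config(cfg, outdir, "dose")
    dose = io.read_dose(simdir / "dose.nii")
    v_cc = float(cfg["v_cc"])
    rows = []
    for subject, grid in load_cohort(simdir):
        for sub in grid.substructures:
            ref = grid.get(sub, "ED", "EE")
            d_ref = structure_d_cc(ref, dose, v_cc)
            for mt in ("cardiac", "respiratory", "cardiorespiratory"):
                irv = io.read_mask(margindir / subject / f"irv_{sub}_{mt}.nii", label=sub)
                d_irv = structure_d_cc(irv, dose, v_cc)
                rows.append(
                    {
                        "subject": subject,
                        "substructure": sub,
                        "motion_type": mt,
                        "d003cc_ref_gy": d_ref,
                        "d003cc_irv_gy": d_irv,
                        "delta_d003cc_gy": d_irv - d_ref,
                    }
                )
    io.write_table(pd.DataFrame(rows), outdir / "d003cc_gy.csv")
    return outdir


def run_stats(cfg: dict, motiondir, outdir, groupings=None) -> Path:
    """Grouping comparisons over the 8 metrics; writes per-grouping results."""
    motiondir, outdir = Path(motiondir), Path(outdir)
    _write_resolved_config(cfg, outdir, "stats")
    table = pd.read_csv(motiondir / "motion_metrics_mm.csv")
    if groupings is None:
        present = set(table["substructure"].unique())
        groupings = {
            name: spec
            for name, spec in stats.DEFAULT_GROUPINGS.items()
            if all(set(subs) <= present for subs in spec.values())
        }
        if not groupings:
            # phantom cohorts carry few substructures; fall back to one
            # grouping per substructure pair
            subs = sorted(present)
            groupings = {"all_substructures": {s: [s] for s in subs}}
    results = stats.compare_groupings(
        table,
        groupings,
        alpha=float(cfg["stats"]["alpha"]),
        min_significant=int(cfg["stats"]["min_significant"]),
    )
    per_metric = []
    for r in results:
        df = r.metrics.copy()
        df.insert(0, "motion_type", r.motion_type)
        df.insert(0, "grouping", r.grouping)
        per_metric.append(df)
    io.write_table(pd.concat(per_metric, ignore_index=True), outdir / "kruskal_wallis.csv")
    io.write_table(stats.summary_matrix(results), outdir / "significance_summary.csv")
    return outdir


def run_full(cfg: dict, outdir) -> Path:
    """simulate -> bin -> motion -> margins -> dose -> stats, one directory."""
    outdir = Path(outdir)
    t0 = time.time()
    simdir = run_simulate(cfg, outdir / "sim")
    run_bin(cfg, simdir, outdir / "bin")
    motiondir = run_motion(cfg, simdir, outdir / "motion")
    margindir = run_margins(cfg, simdir, outdir / "margins")
    run_dose(cfg, simdir, margindir, outdir / "dose")
    run_stats(cfg, motiondir, outdir / "stats")
    with open(outdir / "run.json", "w") as fh:
        json.dump({"seed": cfg["seed"], "elapsed_s": time.time() - t0}, fh)
    log.info("full run complete in %.1f s", time.time() - t0)
    return outdir
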