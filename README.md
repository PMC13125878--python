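# cardio5d

Decoupled cardiorespiratory motion analysis of cardiac substructures from
phase-binned volumetric masks: retrospective cardiac/respiratory bin
assignment from surrogate signals, centroid/bounding-box excursion metrics
(cardiac, respiratory, and hysteresis motion), directed surface-distance
metrics (MDA, HD95), directional internal organ-at-risk margins (IRVs),
DVH / D_0.03cc dosimetric evaluation, and cohort statistics
(Kruskal–Wallis + Dunn over 8 motion metrics).

A synthetic phantom module generates surrogate respiratory/cardiac signals,
moving substructure masks with exact ground-truth displacements, and
synthetic dose grids, so the entire pipeline is testable without any imaging
data.

## Layout

| module | role |
| --- | --- |
| `cardio5d.phantom` | surrogate signals, motion model, mask/dose rendering, cohort simulation |
| `cardio5d.binning` | cardiac phase bins (phase-based) and respiratory states (10/80/10 amplitude split) |
| `cardio5d.structures` | `StructureMask` / `PhaseGrid` data model, centroid, bounding box, geometric valves/nodes |
| `cardio5d.motion_metrics` | decoupled cardiac/respiratory/hysteresis displacements, MDA/HD95, >5 mm flags |
| `cardio5d.margins` | outward directional margins and IRV construction |
| `cardio5d.dosimetry` | dose sampling, DVH, D_v (default D_0.03cc), ΔD |
| `cardio5d.stats` | Kruskal–Wallis + Dunn batteries over substructure groupings |
| `cardio5d.io` / `cardio5d.pipeline` / `cardio5d.cli` | NIfTI/CSV I/O, orchestration, CLI |

Axis convention everywhere: x = RL (+right), y = AP (+anterior),
z = SI (+superior); voxel-center physical coordinates
`origin + spacing * index`. NIfTI volumes are written/read as RAS+.

## CLI

```sh
cardio5d simulate --seed 1 --out out/sim            # synthetic cohort
cardio5d bin      --sim out/sim --out out/bin       # signal binning
cardio5d motion   --sim out/sim --out out/motion    # excursion metrics
cardio5d margins  --sim out/sim --out out/margins   # IRV margins + masks
cardio5d dose     --sim out/sim --margins out/margins --out out/dose
cardio5d stats    --motion out/motion --out out/stats
cardio5d full     --seed 1 --out out/run            # everything
```

All stages accept `--config config.yaml` (merged over built-in defaults;
see `cardio5d.pipeline.DEFAULT_CONFIG`) and `--seed`. Runs are
deterministic for a fixed seed and write their resolved configuration next
to the outputs.

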