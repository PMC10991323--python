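# anttrail

Quantitative analysis of ant **trail-following assays**: videos of single
ants walking in a rectangular arena whose paper floor carries a thin grey
line onto which a candidate trail-pheromone solution has been applied. The
package turns each recording into a per-ant *distance walked on the trail*
and runs the group-level statistics that decide whether a compound — at a
given concentration — recruits ants to the line. It is written for
behavioural ecologists and chemical ecologists running dose–response trail
assays (e.g. comparing a compound across a 10⁻³…10¹ ng/µL concentration
ladder against solvent and blank controls, or two enantiomers against each
other), and for anyone who needs a ground-truthed synthetic benchmark for
single-animal video tracking.

## What it computes

1. **Compression.** Each grayscale recording (720 × 1280 px, 25 frames/s,
   3 min) is binned 4 × 4 in space and 4 frames in time (block means), giving
   ≈1 mm pixels and a 160 ms frame period.
2. **Tracking.** The static scene is estimated as the per-pixel temporal
   median; in every binned frame the ant is the largest sufficiently dark
   connected blob of the difference image, located by its intensity-weighted
   centroid. Short detection gaps are bridged by linear interpolation.
3. **Trail metric.** For every sample the Euclidean distance *d* to the
   closed trail segment is computed; a sample is *on-trail* iff *d* < 5 mm.
   The response variable is

   y = Σ step lengths over steps whose endpoints are both on-trail  (mm),

   together with the total path length and the on-trail time fraction.
   Per-group occupancy heatmaps accumulate all valid samples on a 2 mm grid.
4. **Statistics.** y is transformed to Y = ln(y + 1); a one-way ANOVA tests
   for any dependence on the trail preparation (k groups of n ants give
   df = (k − 1, k(n − 1)); the canonical 13 × 15 design yields (12, 182)),
   Dunnett's two-sided multiple comparisons test each preparation ×
   concentration group against the control, and unpaired t-tests compare
   compounds at matched concentrations.

A fully seeded synthetic generator — correlated random walk with a tunable
heading bias toward the line, an arena renderer, and a log-normal
group-distance sampler — provides ground truth for every stage, so the whole
pipeline is testable without any recordings.

## Worked example

Generate a small synthetic experiment (3 groups × 5 ants, 20 s videos at
reduced 180 × 320 resolution) and analyse it end to end:

```python
import dataclasses
from anttrail import (ArenaConfig, GroupDesign, RunConfig,
                      make_fixtures, run_experiment)

cfg = RunConfig(arena=ArenaConfig(px_per_mm=2.0, duration_s=20.0),
                output_dir="demo", seed=7)
design = GroupDesign(
    groups=(("blank", "-"), ("2-tridecanol", "1e-2"), ("2-tridecanol", "1e1")),
    n_per_group=5,
    effect_profile={("2-tridecanol", "1e1"): 1.5},   # ln-scale shift
    control=("blank", "-"), seed=7)

run_cfg = make_fixtures(cfg, design)     # writes videos + truth CSVs
report = run_experiment(run_cfg)         # tracks, measures, tests
print(report.metrics.groupby("group")["y_mm"].mean().round(1))
a = report.anova
print(f"ANOVA: F({a.df1},{a.df2}) = {a.F:.2f}, p = {a.p:.4g}")
print(report.dunnett.to_frame())
```

Output:

```
group
2-tridecanol@1e-2    101.1
2-tridecanol@1e1     352.8
blank@-               66.0
ANOVA: F(2,12) = 27.51, p = 3.292e-05
            group  mean_diff_ln        t  p_adjusted stars
2-tridecanol@1e-2      0.455301 1.832124    0.158359    ns
 2-tridecanol@1e1      1.774699 7.141361    0.000012  ****
```

Ants on the high-concentration trail walked ~353 mm along the line in 20 s
versus ~66 mm for the blank control; the ANOVA shows a strong overall group
effect, and Dunnett's comparisons flag only the high concentration as
significantly different from control (`****` = adjusted p < 0.0001) — the
dose-dependent recruitment a trail pheromone produces. `demo/` now contains
per-ant trajectory CSVs, per-group heatmap CSV/PNGs, the statistics tables
and a run manifest.

The same pipeline is scriptable from the shell:

```sh
anttrail fixtures -o demo --groups 3 --ants 5 --duration 10
anttrail run -c demo/fixtures/run_config.yaml
```

To analyse real recordings, point the `experiment` table of the run config
at your videos (numbered PNG/TIFF sequences, or containers where an ffmpeg
plugin is available), set `arena.px_per_mm` from your calibration and the
trail-line endpoints in arena millimetres, and run `anttrail run`.

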