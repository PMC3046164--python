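# numotion

Tools for studying **numerosity estimation without luminance cues**: a
stimulus generator for bar displays defined in first-order
(luminance-based) or second-order (contrast-based, drift-balanced) motion,
the **occupancy model** family those stimuli are designed to defeat, a
simulated observer with **scalar variability**, and the standard
psychophysical analysis chain.

## The problem

Whenever the numerosity of a dot display changes, some non-numerical
quantity — spatial extent, density, or a combination of the two — changes
with it. Occupancy models make this concrete: perceived numerosity is
predicted by the area of the union of disk-shaped *influence spheres* of
radius *r* around the items, a quantity computable by simple first-order
spatial filtering of the image. To test whether numerosity estimation
*requires* such luminance-based processing, one needs stimuli with **no
luminance signature at all**: items visible only as coherent second-order
motion, obtained by repeatedly inverting the texel polarity (gray ↔ white)
inside moving item regions of a random binary texture. Any single frame of
such a stimulus is statistically identical to the background, so any
first-order filter — and hence any occupancy computation — returns nothing.

Estimation behaviour itself follows Stevens' power law with scalar
variability:

    ψ = c φⁿ,    SD(ψ) ∝ E[ψ]   (constant coefficient of variation)

where φ is physical and ψ estimated numerosity.

## What is in the package

| module | contents |
|---|---|
| `numotion.geometry` | display model (1024×768 @ 75 Hz, 4-px texels, 30.77 px/°), degree↔texel conversion |
| `numotion.stimulus` | 17×12-grid bar layouts with spacing constraints, random gray/white backgrounds, out-and-back motion paths, first- and second-order frame rendering, PNG/GIF export |
| `numotion.occupancy` | union-of-disks occupancy (raster + Monte-Carlo oracle), density-normalized variant, disk-kernel spatial filtering of frames |
| `numotion.observer` | power-law observer with constant-CV lognormal noise, per-condition gains; power-law fitting |
| `numotion.psychstats` | scalar-variability diagnostics, per-subject standardized multiple regressions, two-way repeated-measures ANOVA with partial η², cross-condition correlations |
| `numotion.session` | calibration/practice/proper trial schedules, end-to-end session runner |
| `numotion.cli` | `numotion generate-stimuli / occupancy / simulate / analyze / session` |

## Worked example

Simulate the default within-subjects experiment (11 subjects × 2 motion
conditions × numerosities 10–30 × 6 repetitions) and run the analysis
chain:

```python
import numotion as nm

table = nm.simulate_estimates(range(10, 31), subjects=11, reps=6,
                              params=nm.ObserverParams(), seed=7)
rep = nm.scalar_variability_report(table)
for cond in ("first_order", "second_order"):
    d = rep.per_condition[cond]
    print(f"{cond}: slope(log SE ~ log mean) = {d.slope_log_se_log_mean:.2f}")
print(f"CV vs mean estimate: R^2 = {rep.cv_vs_mean_r2:.4f}, "
      f"mean CV = {rep.mean_cv:.2f}")
anova = nm.rm_anova_2way(table)
e = anova.order
print(f"order: F({e.df_num},{e.df_den}) = {e.F:.2f}, "
      f"partial eta^2 = {e.eta_sq_partial:.2f}")
```

prints

```
first_order: slope(log SE ~ log mean) = 0.98
second_order: slope(log SE ~ log mean) = 1.04
CV vs mean estimate: R^2 = 0.0013, mean CV = 0.30
order: F(1,10) = 35.96, partial eta^2 = 0.78
```

The SE-vs-mean slope near 1 and the flat CV are the signature of scalar
variability (estimating, not counting); the ANOVA on log cell means tests
the motion-order condition against its subject interaction with the
design's (1, 10) degrees of freedom.

Rendering one second-order trial and probing it with the filtering model:

```python
g = nm.DisplayGeometry()
layout = nm.sample_layout(20, g, seed=1)
seq = nm.render_second_order(layout, nm.motion_path(g), geometry=g,
                             texture_seed=5)
nm.filter_occupancy(seq.frames[0], nm.OccupancyParams(r=0.5), g)  # -> 0.0
```

Every second-order frame contains only gray and white texels, so the
occupancy filter returns 0 at every numerosity — while the same probe on a
first-order frame grows monotonically with the number of bars.

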