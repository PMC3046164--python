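# Methods

## Display model and units

All stimulus dimensions are degrees of visual angle; rendering happens on
a texel raster. The default `DisplayGeometry` is a 1024×768 display at
75 Hz tiled with 4×4-pixel texels, viewed so that one degree is 30.77
pixels (a 17″ 4:3 panel at 58 cm). Under this convention the 0.13° bar
width is exactly one texel column, which is why 30.77 px/° is the default
rather than a rounder number; it is configurable. Luminance is coded
black = 0, gray = 128, white = 255 on the 8-bit scale; no gamma model is
applied, and no physical cd/m² calibration is implied.

`deg_to_texels` rounds half away from zero. At the defaults: 0.13° → 1
texel, 0.98° → 8, 1.84° → 14, 2.08° → 16, 3.12° → 24.

## Layouts

A trial's layout places N vertical bars (width 0.13°, height 2.08° or
3.12°, each with probability ½) on a 17×12 imaginary grid covering the
screen (cell pitch = screen extent / grid dimension, origins snapped to
texels). Placing at most one bar per cell guarantees the pairwise spacing
rule, formalized as a disjunction on bar centres: for every pair,
horizontal distance ≥ 1.84° **or** vertical distance ≥ 0.98°. A 14-texel
(1.84°) margin at the right screen edge is kept free for the motion
excursion; the rightmost grid column still fits exactly.

Sampling is by per-bar rejection with a global 10 000-attempt budget: a
draw of (cell, height) whose bar would leave the screen — a 3.12° bar
anchored in the bottom grid row — is simply redrawn. Consequences worth
knowing: heights are i.i.d. uniform *conditionally on feasibility*, so
bottom-row bars are always short; and because the spacing rule constrains
centres, a tall bar can physically abut or overlap a bar in the cell
directly below its own column. Both are properties of the grid-based
placement scheme, accepted as-is. Validity is always checkable with
`verify_layout`, a brute-force pairwise verifier independent of the
sampler's bookkeeping.

Numerosities 10–30 are the intended operating range; any n from 1 to the
grid capacity of 204 is accepted, beyond which a capacity error names the
offending n.

## Motion

Bars move 1.84° rightward and back within a 133 ms visible epoch —
round(0.133 × 75) = 10 frames. The speed profile within the excursion is
not constrained by the design, so the path is the symmetric choice: 5
frames out, 5 back, per-frame offsets snapped to whole texels
(0, 4, 7, 11, 14, 14, 11, 7, 4, 0), the rounding residual absorbed at the
turnaround. Peak excursion is 14 texels = 1.82°, within half a texel of
the nominal 1.84°. First and last offsets are zero and net displacement
over the sequence is zero.

## First- and second-order rendering

The background is a full-screen field of i.i.d. gray/white texels
(p = ½ each; the generating texture is assumed symmetric). First-order
frames copy the background and paint every bar footprint black at the
current offset; after the epoch the untouched background remains
("disappearance"), so mean luminance strictly decreases with total bar
area and hence with numerosity.

Second-order frames follow the drift-balanced recipe: maintain a texture
state, and at each frame flip the polarity (gray ↔ white, v → 383 − v) of
every texel inside each bar's current footprint, then move on. The state
persists (`state_mode="evolving"`), so texels behind a departed bar may
stay inverted — that is what the recipe prescribes; an alternative
`"reset"` mode inverts each frame relative to the fixed background. In
both modes no texel is ever black, and because gray and white are
exchangeable under Bernoulli(½), inversion preserves every texel's
marginal distribution: across texture seeds, any single frame of any
layout is distributionally identical to the background. Numerosity is
carried **only** by the spatiotemporal structure of the flips. The
test suite checks the frame-to-frame difference maps against independent
flip bookkeeping, and the marginal-preservation and two-layout
indistinguishability properties empirically.

## Occupancy models

`union_disk_area` rasterizes the union of radius-r disks (pixel-centre
inclusion) at 0.02°/pixel by default; a Monte-Carlo estimator
(`union_disk_area_mc`, 10⁶ samples by default) serves as an independent
oracle, and the two agree within 1 % on small configurations. Items with
rectangular extent (bars) use the distance-to-rectangle test, i.e. the
Minkowski sum of rectangle and disk, which reduces to the plain disk for
point items.

The density-adaptive variant shrinks the influence radius with density d
via r(d) = r₀ / (1 + k·d) — any positive non-increasing function is
accepted; this default is bounded and monotone — and normalizes occupancy
by the influence-sphere **area** πr², so n disjoint spheres score exactly
n and n coincident ones score 1. The density region defaults to the
items' bounding box and can be set explicitly. Because the rasterized
union is accurate to ~0.1 %, "exactly" holds to that tolerance.

`filter_occupancy` is the image-domain route: threshold the frame at
black to get the item mask, convolve with a binary disk and count the
strictly positive response — equal to the mask dilated by the disk. The
disk uses the pixel-extent convention (offsets with
x² + y² ≤ (r + ½)²): with a coarse 0.13°-texel raster, the naive
centre-inclusion disk systematically under-covers by most of a texel ring
(for a typical bar that is a ~20 % area deficit at r = 0.5°), whereas the
half-pixel convention keeps the raster area within a texel-row of the
geometric Minkowski area. On second-order frames the mask is empty and
the result is identically 0 at every numerosity — the filtering route is
blind to contrast-defined items by construction.

## Simulated observer

Estimates follow ψ = gain_cond · c · φⁿ · exp(ε) with ε ~ N(0, σ²),
σ = √log(1 + cv²), so the multiplicative noise has a constant coefficient
of variation — the minimal generative model for scalar variability.
Responses are rounded to the nearest integer with a floor of 1, mirroring
typed numeral responses. Note ε is zero-mean in log space, so the
arithmetic mean response exceeds c·φⁿ by the lognormal factor
e^{σ²/2} ≈ 1.05 at cv = 0.33; fits and diagnostics are done in log space
where this is an intercept shift.

Defaults, chosen once as the study conditions: cv = 0.33 (the human CV
level for this task); exponent n = 0.85, a typical compressive value for
numerosity estimation; c = 20^0.15 so that ψ(20) = 20 — calibration
feedback at numerosity 20 anchors accuracy there, which makes small
numerosities overestimated and large ones underestimated; condition gains
1.1 (first-order) vs 1.0 (second-order), reproducing the higher
first-order estimates. An optional per-condition exponent offset (default
0) produces an order × numerosity interaction; optional per-subject
jitter on log c and n (default 0) produces inter-subject spread. Each
trial's mean bar height is drawn as the mean of N i.i.d. fair choices
between the two height classes, matching the layout statistics without
rendering.

The generator emulates the *statistical* structure of estimation data —
power-law means, constant CV, condition gains, complete within-subjects
designs. It does not emulate sequential effects, lapses, eccentricity- or
crowding-dependent sensitivity, subject exclusions, or any genuine
perceptual difference between the motion orders beyond the gain; passing
diagnostics on simulated tables therefore validates the analysis chain
and the generative assumptions, not human behaviour.

## Analysis chain

**Scalar variability.** Per (condition, numerosity), the group mean
estimate and its between-subject SE (SD of the 11 subjects' cell means /
√11; `se_convention="pooled"` uses the SD of all raw estimates in the
cell instead). The diagnostic regression of log SE on log
mean estimate has slope ≈ 1 under constant CV and slope ≈ 0 under
additive constant-SD noise. CVs are computed per (subject, condition,
numerosity) cell over its repetitions (cells with one observation are
excluded with a warning); the flatness regression uses each cell's CV
against the **across-subject mean** estimate of its cell. The regressor
choice matters: a cell's sample CV and its own sample mean are computed
from the same 6 draws and are positively correlated for lognormal samples
(r ≈ 0.20 at cv = 0.33), which by itself inflates the pooled R² to ≈ 0.011
even when the true CV is perfectly flat — a shared-noise (spurious ratio
correlation) artifact. Against the cell-independent group mean the
100-seed average R² is ≈ 0.002, at the null level. Both numbers are
reported (`cv_vs_mean_r2`, `cv_vs_cell_mean_r2`). Per-numerosity bias
tests (mean estimate − φ across subjects) are reported uncorrected with a
Bonferroni column alongside.

**Per-subject regressions.** log estimate on log numerosity and log mean
bar height, all three z-scored first so the coefficients are
standardized (the standardization convention is the package's choice).
Residual df is the standard nobs − 3; for the 126-trial per-condition
design that is 123. Constant predictors raise an error naming the
predictor, using a relative tolerance so that a log-constant column with
float jitter is still caught.

**Repeated-measures ANOVA.** Repetitions are collapsed to cell means per
(subject, condition, numerosity) — required for the (20, 200) numerosity
df with 11 subjects — log-transformed, and decomposed by classical
within-subjects sums of squares; each effect is tested against its own
subject-interaction mean square, with partial η² =
SS_effect/(SS_effect + SS_error). No sphericity correction is applied;
the uncorrected df are the design's. A hand-computable oracle and
pingouin both confirm the implementation in the test suite; missing cells
raise an error listing them.

**Cross-condition agreement.** Per subject, repetitions are averaged per
numerosity within each condition and the 21 pairs correlated (Pearson).
Zero variance in either condition yields NaN with a warning rather than
an error.

## Sessions

Per condition: 3 calibration trials at numerosity 20 with a feedback flag
(the feedback numeral is recorded in the schedule, not drawn into
exported frames), 40 practice trials with numerosities sampled uniformly
**with replacement** from 10–30, then a seeded uniform permutation of the
21 × 6 proper trials. Whether practice belongs to each condition block or
is shared is ambiguous in a two-condition blocked design; the default is
per-condition (parallel to the per-condition calibration), with
`practice_per_condition=False` and `interleave_conditions=True` switches
for the alternative readings. Every trial carries its own derived layout
and texture seeds (all below 2³¹), so the whole session is reproducible
from the master seed and layout draws are independent across trials.

## Problem sizes and numerical choices

The shipped diagnostics use the design's own scale (11 subjects × 2 × 21
× 6; 100 simulation seeds; 200 texture seeds per layout for the
invisibility test; 10⁶ Monte-Carlo samples), which completes in seconds.
Union-area rasters default to 0.02°/pixel (~0.1 % area error on
unit-scale disks). Ties in `deg_to_texels` round half away from zero.
Degenerate inputs are reported, not crashed on: noiseless tables give a
degenerate scalar-variability fit, empty filter masks give area 0, and
zero-variance correlations give NaN.

## Known limitations

- The spacing rule constrains bar centres via grid cells; tall bars in
  vertically adjacent same-column cells can touch or overlap.
- Bar heights are uniform only conditionally on on-screen feasibility
  (bottom grid row is short-bar-only).
- The observer's mean response carries the lognormal e^{σ²/2} factor; c
  is therefore a log-space constant, not the arithmetic-mean scale.
- The occupancy models are implemented for static point/bar
  configurations and single frames; no temporal (rate-based) occupancy is
  provided.
- Rendering is frame-accurate but not display-accurate: no gamma, no
  timing jitter, no eye movements.
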