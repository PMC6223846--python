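# Methods

This note documents the models, numerical choices and limitations behind
`zetafish`. Units are centimetres and seconds throughout; the coordinate
origin is the front-bottom-left corner of the fish compartment, x along
the long tank axis, y along the short axis, z up.

## Experimental frame and protocol constants

The geometry defaults describe the fish's front compartment of a standard
training tank: 20 × 9.5 cm footprint, 6 cm water column, a floating
feeding ring (radius 2.25 cm) in the front corner, an inflow tube at
half-height near the front wall, and a reward zone — the rectangle
bounding the ring, spanning the full short axis and covering one third of
the footprint. The surface-sampling threshold sits at 70% of the water
column.

The default protocol delivers nine CS+ and nine CS− odor presentations
per day in alternating order at 20-min inter-trial intervals; food arrives
30 s after CS+ onset. Three analysis windows surround each onset: a 30-s
baseline ending at onset, a response window from onset to food delivery
(30 s), and a reference window of response length immediately before the
baseline, so reference and response are equidistant from the baseline.

## ζ transform

Per fish and parameter, trial series are transformed in three steps:
(1) subtract each trial's baseline-window mean; (2) subtract the
unweighted mean of the CS+-average and CS−-average series from every
trial's series (unweighted so unbalanced class counts do not bias the
center; with the balanced protocol this equals the grand average);
(3) divide all of the fish's series for that parameter by the sample SD
(ddof 1) of time-averaged reference-window values, pooled across trials
of both classes. Pooling matches the stimulus-free character of the
reference window — splitting by class would halve the sample for no
benefit and break under unbalanced designs. A zero reference SD (e.g. a
parameter that never varies) is a degenerate fish and raises an error
naming the parameter rather than producing infinities.

Signs for Distance and Circling are inverted *after* the transform and
before composite scoring, so positive ζ is always "more appetitive".
Binary parameters (Area, Surface) pass through the identical pipeline on
their 0/1 frame series; window averaging turns them into occupancy
fractions and event rates implicitly. ζ values are related to z-scores
but normalized to a fixed pre-stimulus window, so they are not calibrated
z-scores and are never interpreted as such.

The composite score is ζ_comp = Σζᵢ/√6 (Stouffer). The covariance-weighted
variant uses wᵢ = Cᵢᵢ/ΣⱼCᵢⱼ with C estimated from the whole cohort's trial
scores (per-fish mean-centered before pooling so between-fish offsets do
not inflate covariance); the weighted sum is divided by √(Σwᵢ²) so that it
reduces exactly to ζ_comp for uncorrelated, equal-variance parameters.
Only the weights are dictated by the covariance recipe; the √(Σwᵢ²)
renormalization is this package's scale convention.

## Circling index

For every 1-s bin, the 30-s x-position segment centered on the bin
(edge bins clamp to the nearest full window) is mean-detrended, tapered
with a Tukey window (shape 0.25), and its periodogram integrated over
0.029–0.146 Hz. The index is band power divided by total power excluding
the DC bin — the denominator is a package choice; excluding DC makes the
index scale- and offset-invariant and bounded in [0, 1]. An all-constant
segment is defined as 0 (no oscillation). The centered (rather than
trailing) window placement keeps the index phase-aligned with behavior.

## Surface-sampling events

An event is an upward crossing of the z threshold while the fish is
horizontally within the feeding ring. Crossings are inherently
hysteretic — z must fall below threshold before a new event — which
debounces sensor-level chatter without a tunable refractory constant.

## Tracking

Background: per-pixel median over frames (deterministic, robust to the
moving fish). Threshold: Otsu on the clipped background-subtracted image,
floored at an absolute value of 10 grey levels to avoid noise-driven
thresholds on empty frames. The largest connected component above a
minimum area is reduced to its intensity-weighted center of gravity
(negligibly different from the binary centroid for compact blobs, but the
weighted form is the declared convention). Fusion takes x, y from the top
view and z from the side view; the side view's x serves only as a
consistency check — frames disagreeing by more than 0.5 cm are flagged
and the top view trusted. Detection gaps are linearly interpolated; gaps
longer than `max_gap_frames` (default 10) are filled too but flagged per
frame so downstream users can exclude them.

## Synthetic behavior generator

The generator is a stochastic kinematic model, not a biomechanical one.
Spontaneous behavior is wall-following circling: an elliptical orbit
1 cm inside the walls traversed at `baseline_circle_freq_hz` (default
0.05 Hz, inside the 0.029–0.146 Hz band), with the orbit scaled so mean
path speed matches `baseline_speed_cms` (2 cm/s), an Ornstein–Uhlenbeck
(OU) modulation of angular rate (SD 0.20, τ 20 s), 5% amplitude wobble,
an OU cruising-depth fluctuation around 0.35 of the water column (SD
0.35 cm, τ 5 s), and isotropic positional noise (OU, SD `noise_sd` =
0.15 cm, τ 0.7 s).

During a response episode with strength *s* the six appetitive components
are expressed as: angular rate raised so path speed increases additively
by `speed_cms·s`; z raised by `zlevel_cm·s`; position blended toward the
ring center with weight `area·s` and toward the inflow with weight
`inflow·s`; surface-sampling excursions as a Poisson process at
`surface_hz·s` (each a ~2.6-s dash to the ring center with a 1.2-s z
excursion peaking at 0.9 of the water column, starting and ending below
threshold so the event counter sees exactly one crossing); and circling
suppressed by shrinking the orbit by `circling·s` while adding incoherent
zigzag swimming at 0.45–0.6 Hz, above the circling band. Responses begin
strictly at odor onset (trapezoidal envelope, 2-s ramps), which is what
the pre-odor control exploits.

Learning follows g(k) = 1 − exp(−`learning_rate`·k) on the k-th trial of
a class; the default rate 0.125/trial approaches saturation after ~27
trials per class, i.e. about three training days under the default
protocol. CS− responses are scaled by `cs_minus_gain_frac` (0.10; weak
but not absent). Each trial's response is additionally scaled by a
mean-one gamma amplitude with coefficient of variation 1.1, reflecting
the observation that the contribution of behavioral components varies
strongly between trials; spontaneous surface sampling occurs at 0.015 Hz
so the Surface parameter has nonzero stimulus-free variability (a zero
reference SD would otherwise make the ζ transform degenerate — as it
does for real fish that never sample spontaneously).

Default response gains (speed 0.20 cm/s, z 0.15 cm, area 0.08, surface
0.02 events/s, inflow 0.035, circling 0.15) were calibrated once so that a simulated cohort reproduces the
magnitude regime reported for real cohorts: end-of-training d ≈ 1 with
per-fish SEM ≈ 0.2–0.3, two-day 12-fish discrimination d ≈ 0.7 at
p ≈ 0.02, and per-day significance emerging on day 1–2. These are
calibration knobs, not estimates — no quantitative distribution of
spontaneous zebrafish behavior was available to fit.

Three scenarios: `learning` (as above), `null` (identical schedule, all
response gains forced to zero — CS+ and CS− trials are then statistically
identical by construction), and `unpaired` (odors evoke nothing; food
arrives after either odor with probability 0.5 and feeding behavior is
expressed at the delivery itself; trials carry odor labels for later
random balanced CS assignment).

Determinism: one `numpy` generator seeded from `BehaviorModel.seed` drives
every draw in a fixed order, so identical seeds give bit-identical
trajectories; cohort members get child seeds from a root generator.

## Statistics

Wilcoxon signed-rank (d vs 0) uses the exact null distribution up to
n = 25 and the normal approximation with continuity correction above;
rank-sum comparisons use Mann–Whitney U with the same exact/asymptotic
switch. Pooled rank-sum tests treat trials from one fish as independent
observations, mirroring how "all individual trials" are compared in this
paradigm; this overstates effective sample size when fish differ
systematically and the per-fish signed-rank test is the primary
inference. Per-day significance flags are not corrected for multiple
comparisons across days. "Last 12 trials" means the last 12 trials *of
each stimulus class* (a config knob, `n_last`).

The unpaired control operates on trial scores labeled by odor: because
class-mean centering subtracts the same series from every trial and the
reference SD pools all trials, reassigning CS labels only shifts all
ζ_comp values of a fish by a common constant — so d and both rank tests
from a relabeled score table are identical to a full re-run of the ζ
pipeline under that assignment, and the control can reuse the scored
table.

## Problem sizes and what the tests show

Tests and the acceptance script simulate with a compressed inter-trial
interval of 160 s (versus 1200 s in the protocol) and a compressed
unpaired food delay of 60 s (versus 15 min). The analysis windows need
only ~120 s of pre-onset coverage per trial, every ζ statistic is
invariant to the interval length, and food-evoked episodes in the
unpaired scenario still fall outside all analysis windows, so the
compression changes cost, not content. Cohort sizes follow the study
conditions: 62 fish for the pooled analyses and the pre-odor control,
16 for the unpaired control, 12 for the learning-curve cohort.

Passing tests demonstrate that the pipeline is unbiased (null and
unpaired scenarios yield d ≈ 0 and no spurious significance), sensitive
(simulated learning produces the expected d magnitude, day-level
significance and gain-monotonicity), and numerically correct against
independent oracles. They do not validate the generator as a model of
real zebrafish: real trajectories contain posture, wall-proximity and
social-history structure, non-Poisson surface sampling, and slow
motivational drifts that the generator does not emulate; conclusions
about real data rest on the analysis code, not on the simulator's
realism.

## Known limitations

- The tracker is single-animal, offline, and assumes a bright fish on a
  darker, stationary background; it does not maintain identity across
  occlusions or estimate heading.
- The circling index inherits periodogram leakage: power exactly at the
  band edges is attributed by FFT bin (window 900 samples, bin width
  1/30 Hz), so the band effectively covers bins at 0.033–0.133 Hz.
- The weighted composite needs a cohort-level covariance; for small
  cohorts the weights are noisy and the unweighted ζ_comp is preferred.
- The generator's components interact (e.g. ring attraction also lowers
  measured speed variability), as real behavioral components do; the
  per-component gains are therefore not orthogonal dials.
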