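# Methods

## Problem and measurement model

The package quantifies movement quality of repetitive 3D reaching
(lap → mouth → lap, as in the SIAS Knee-Mouth assessment) from optical
motion-capture position data: an N×3 series in millimetres, uniformly
sampled (200 Hz typical). Two families of metrics are computed.

**Spatial smoothness.** Instantaneous curvature is evaluated from
velocity and acceleration,

κ = √[ (|v|²|a|² − (v·a)²) / |v|⁶ ]   (1/mm),

the inverse radius of the osculating circle. Because κ is a Euclidean and
time-reparametrisation invariant of the path, it isolates *where the hand
went* from *how fast it went*. The per-session score **MedianLC** is the
median of −ln κ over samples whose speed exceeds a gate (50 mm/s
default). The gate removes movement reversals, where the speed vanishes
and curvature diverges for every mover; the median (not the mean) makes
the score robust to the remaining heavy upper tail of −ln κ near smooth
path sections (κ → 0 ⇒ −ln κ → ∞; exact zeros are excluded as
non-finite). At least 10 gated finite samples are required.

**Temporal smoothness.** Jerk magnitude J = ‖d³x/dt³‖ is summarised two
ways. MedianLJ is the median of ln J over the same gated samples; it is
reported but known to confound irregularity with speed (jerk scales as
duration⁻³). The normalised **MSJ ratio** is computed per stroke:
MeanJ² = (1/d)∫J² dt over the stroke, divided by C·A²/d⁶ with amplitude
A (endpoint displacement, mm) and duration d (s). The integral uses the
trapezoidal rule on the stroke's samples.

### The normaliser constant C

Default C = 360. The classical minimum-jerk stroke
x(τ) = A(10τ³ − 15τ⁴ + 6τ⁵) has jerk polynomial (A/d³)(60 − 360τ + 360τ²)
whose squared integral over [0,1] is 720, so MeanJ² = 720·A²/d⁶ and an
ideal stroke scores **ratio 2** under C = 360. A `normalizer_const=720`
(`--normalizer 720`) option selects the convention in which the ideal
stroke scores 1. The default keeps C = 360 because that is the
established form of the normaliser in the clinical-kinematics literature
this package follows; only the constant offset ln 2 in the log-ratio is
affected, and the choice is recorded in every report.

## Pipeline and parameters

`analyze()` runs: window clip → low-pass filter → principal-axis
rotation → differentiation → curvature metrics → stroke segmentation →
jerk metrics. All parameters, defaults, and rationale:

| parameter | default | meaning |
|---|---|---|
| `window_start_s`, `window_duration_s` | 0, full record | analysis window; clinical practice windows a 30 s recording to a stable 15 s portion free of marker drop-outs |
| `cutoff_hz` | 8 | Butterworth low-pass cut-off; hand-movement content above 8 Hz is tremor/marker noise |
| `filter_order` | 4 | Butterworth order; applied forward–backward (zero phase), squaring the magnitude response |
| `diff_scheme` | forward | two-point differencing, out[i] = (in[i+1] − in[i])·rate; `central` (3-point) available |
| `speed_gate_mm_s` | 50 | tangential-velocity gate for MedianLC / MedianLJ |
| `seg_frac` | 0.1 | stroke threshold as a fraction of the window's maximum speed |
| `min_amp_mm` | 100 | strokes below this endpoint displacement are failed segmentation |
| `min_samples` | 5 | minimum run length; discards threshold chatter (jerk integration needs ≥ 3 samples, 5 adds margin) |
| `normalizer_const` | 360 | C in the MSJ normaliser (see above) |

Numerical choices:

* **Zero-phase filtering** keeps filtered extrema time-aligned with the
  raw movement, so the speed gate and segment boundaries are not lagged.
* **Differentiation and alignment.** Each forward difference shortens the
  series by one; after the third derivative, velocity, acceleration and
  jerk are truncated to the common length N−3 so one index refers to one
  leading sample window. Speed (and hence gating and segmentation) is
  computed from the filtered positions.
* **Curvature guards.** The numerator |v|²|a|² − (v·a)² is non-negative
  by Cauchy–Schwarz but can round below zero; it is clamped at 0. An
  ε = 10⁻¹² (mm/s)² guard on |v|² keeps rest samples finite (the gate
  excludes them anyway).
* **Segmentation ties.** Runs are defined by speed ≥ threshold, so
  boundary samples are included deterministically. A lap→mouth→lap cycle
  with a speed dip at the mouth yields two strokes; amplitude is endpoint
  displacement, not path length, because the normaliser is defined for a
  point-to-point movement.
* **Discretisation accuracy of the MSJ ratio.** Because the forward
  scheme drops 3 samples at the series end — where a stroke's jerk is
  maximal — the MSJ ratio of an ideal stroke converges to 2 from below
  as sampling becomes finer relative to stroke duration: 1.77 at 200
  samples/stroke, 1.975 at 2000, 1.99 at 5000. Analytic verification is
  therefore done at ≥ 2000 samples per stroke; at clinical rates the
  bias is shared by all sessions analysed with the same settings and
  cancels in comparisons. Duration-invariance of the ratio likewise
  holds at fixed samples-per-stroke.
* **Degenerate inputs.** All-rest recordings, windows outside the
  recording, too-few gated samples, zero retained segments, and
  zero-variance positions raise typed errors rather than returning
  sentinels; a session that cannot be segmented (continuous movement) is
  reported as `mean_log_msj_ratio = None` by `analyze()`, mirroring how
  such participants are excluded from jerk statistics clinically.

## Synthetic sessions

`generate_session()` emulates the clinical task so the metrics can be
validated against ground truth:

* **Path**: a circular arc (chord = amplitude, default 400 mm; sagitta =
  `arc_height_frac`·amplitude, default 0.15) bowed out of the movement
  axis along a fixed oblique direction. A circular arc has constant
  curvature, so a clean session has a single analytic MedianLC,
  ln R ≈ 5.90 at the defaults — in the healthy range observed clinically.
* **Timing**: alternating minimum-jerk strokes (comfortable 1.0 s / fast
  0.5 s / slow 2.5 s presets) separated by 0.3 s rests, 8 cycles by
  default, 200 Hz; rests hold the endpoint exactly still so segmentation
  boundaries are unambiguous.
* **Sub-movement corruption**: the standard superposition account of
  paretic reaching — short corrective pulses added to each stroke. Each
  pulse is a there-and-back minimum-jerk bump (duration 0.25 s,
  amplitude 0.25·A·U(0.3,1), uniformly random onset and 3D direction).
  Pulse counts per stroke are Poisson(`corruption_level`), realised as a
  unit-rate birth process truncated at the level, with per-stroke RNG
  streams: for a fixed seed, the pulses present at a lower level are
  exactly a subset of those at a higher level, and sensor noise lives on
  its own stream. Corruption sweeps therefore compare physically nested
  sessions (common random numbers) while each level's marginal
  distribution is unchanged.
* **Sensor noise**: i.i.d. Gaussian per axis, default 0.5 mm, emulating
  optical marker jitter.
* **Presets**: `paretic_mild` / `paretic_severe` set corruption 1 / 3
  and noise 1.0 mm. These are calibration points for ordering behaviour
  (severe < mild < healthy MedianLC), not fitted patient models.

What the generator does **not** emulate: biomechanical arm dynamics and
joint constraints, spasticity-induced velocity asymmetries, tremor with a
spectral peak, marker occlusion gaps, or session-to-session learning.
Passing simulation tests therefore shows the metrics respond correctly to
controlled spatial/temporal corruption — not that they capture every
property of real paretic movement; the clinical worked examples anchor
the latter.

### Observed simulation behaviour

With the defaults, across seeds: MedianLC decreases strictly with
corruption level (0 / 0.5 / 1 / 2) in 20/20 seeds and the mean log MSJ
ratio increases strictly in 19/20; paretic-severity ordering holds
20/20. Slowing the clean movement (slow vs comfortable preset) raises
the mean log MSJ ratio by ≈ 4.7 while MedianLC changes by ≈ 0.45
(≈ 7.8% — entirely a sensor-noise effect: with noise disabled the
contrast is exactly 0, since curvature is speed-invariant and the arc's
curvature is constant). At slow speeds the same positional noise is a
larger fraction of the velocity/acceleration signal, so noise inflates
measured curvature more; shrinking noise toward realistic optical-capture
levels (≲ 0.1 mm) shrinks the gap proportionally. Problem sizes used in
tests and the acceptance script: 8-cycle sessions (≈ 21 s at 200 Hz),
20 seeds per property.

## Statistics

* `spearman_rho`: average ranks for ties (Pearson correlation of rank
  vectors), pairwise deletion of missing values; undefined for < 3
  complete pairs or zero rank variance.
* `split_half_icc`: ICC(2,1) by default — two-way random effects, single
  measurement, absolute agreement, from the ANOVA mean squares — the
  appropriate form for test–retest of a single instrument; ICC(1,1)
  selectable.
* The packaged clinical table keeps the healthy control H1 in the
  correlations by default (matching the published convention of plotting
  patients and control together); `include_h1=False` gives the
  patients-only alternative. Group medians/means exclude H1, which
  anchors the top of the scale.
* Group-difference hypothesis tests (Kruskal–Wallis, Wilcoxon) are
  deliberately not reimplemented; use scipy/pingouin directly on the
  table.

## Known limitations

* The CSV reader requires gap-free uniform sampling; marker-occlusion
  gaps must be windowed out upstream (no interpolation is attempted).
* MedianLC depends on the measurement unit of κ (1/mm throughout); values
  are comparable only between analyses in the same units.
* The forward-difference scheme trades accuracy for fidelity to
  established clinical practice; at 200 Hz the absolute MSJ ratio carries
  a known downward discretisation bias (see above).
* Split-half consistency of MedianLC within a single recording requires
  raw data of sufficient duration; the packaged table only supports the
  between-session ICC worked example.
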