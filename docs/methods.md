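# Methods

`tremorkit` implements the sensor-analysis computation of a within-subject
protocol for wrist-worn vibratory stimulation of Parkinsonian action tremor:
participants draw and write on a digitizing tablet under three vibration
intensities (none, low/sham ~0.38 g, high ~1.51 g) while wearing wrist
accelerometers, and each outcome is compared across intensities with a
random-intercept mixed model.  Because no participant recordings are public,
the package ships a synthetic-data generator that reproduces the statistical
structure the analysis assumes; every stage is validated against analytic
oracles and parameter-recovery simulations on that generator.

## Tablet kinematics

A pen trace is an ordered series of `(t, x, y, pen)` samples; maximal
pen-down runs define strokes.  Per stroke:

1. Euclidean displacement between consecutive samples is accumulated into a
   distance-traveled series.
2. The distance series is linearly interpolated onto a uniform 142 Hz grid
   anchored at the stroke's first timestamp (142 Hz is the tablet's median
   sampling rate; the grid never extrapolates past the last sample).
3. Pointwise velocity is the resampled distance increment times 142 Hz.
4. The velocity profile is smoothed with a 3.5 Hz-cutoff, 5th-order low-pass
   Butterworth filter.

Outcomes: task duration (first stylus-down to last stylus-up, pauses
included), pause count and summed pause time (stylus lifts between strokes),
mean velocity (mean over all in-stroke samples; pauses contribute none),
peak count (strict local maxima of the smoothed profile, compared without
any amplitude threshold), and scaled peaks = peaks / duration.

Numerical choices:

- **Per-stroke processing.** Resampling, differentiation, and smoothing stay
  inside each stroke, so no fictitious velocity spans a pen lift.
- **Filter phase.** The tablet chain defaults to a single forward pass; a
  `zero_phase` switch applies forward–backward filtering (squared magnitude
  response, zero lag) to match the accelerometry convention.
- **Filter initialization.** The single-pass filter is initialized at the
  stroke's first value (steady-state initial conditions), so a constant
  profile passes through unchanged and no start-up transient is counted as
  spurious peaks.
- **Tie-break.** A velocity peak requires strict inequality on both sides;
  flat-topped plateaus are not counted.  This is the simplest reproducible
  reading of neighbouring-value comparison with no threshold.
- **Short strokes.** Strokes shorter than 18 resampled samples
  (3 × (order + 1)) cannot satisfy the filter's edge requirements; their raw
  velocity is used and the repetition is flagged (`n_unsmoothed_strokes`)
  rather than silently dropped.

Because the peak rule has no amplitude threshold, residual sub-pixel ripple
in a smoothed profile still counts; peak counts on simulated data are
therefore higher than on hardware traces whose quantization flattens such
ripple.  The filter's measured gain is verified against the closed-form
magnitude of the bilinear-transform digital Butterworth,
`|H(f)| = (1 + (tan(pi f/fs)/tan(pi fc/fs))^(2n))^(-1/2)`; this is the
response of the filter actually applied (the analog prototype formula
deviates from it by up to ~4% relative in the deep stopband because of
bilinear frequency warping).

## Accelerometry features

Streams are tri-axial, 128 Hz, in g.  Stream/task synchronization uses clap
bursts: the power series is the squared magnitude of the mean-removed
3-axis vector (g²); a clap starts at the first sample of a run of at least
110 consecutive samples with power ≥ 0.17.  The task segment starts a
configurable offset (default 1 s) after the clap ends.

Acceleration is low-pass filtered per axis with a zero-phase 3.5 Hz
5th-order Butterworth; jerk is the first difference times the sampling rate
(g/s, length n−1).  For each axis of acceleration and jerk, 32 features:

- mean;
- Hjorth mobility `sqrt(var(dx·fs)/var(x))` (≈ 2πf for a pure tone, a mean
  angular-frequency proxy) and complexity `mobility(dx·fs)/mobility(x)`
  (1 for a pure tone, a bandwidth proxy);
- roughness, the sum of squared second differences (curvature energy), and
  rugosity, the RMS of first differences — the conventions of the seewave /
  mhealthtools lineage, since the metric names come from that toolchain;
- spectral entropy of the Hann-window periodogram's positive-frequency
  probability distribution, normalized by log(bin count) into [0, 1];
  mean frequency `sum f·p(f)`; and the energy in twenty-four consecutive
  0.5 Hz bands starting at 2 Hz.  A "24 half-Hz bands between 2 and 12 Hz"
  description is internally inconsistent (that range holds twenty); the
  count is what the 32-feature total requires, so the grid runs 2–14 Hz;
- fluency: the strict-local-maximum peak count of the tablet rule,
  normalized by segment duration (the 32nd feature; the raw count is kept
  as a bookkeeping column).

**Spectral input.** Band energies to 14 Hz are uninformative after a 3.5 Hz
low-pass, so by default the time-domain features (mean, Hjorth, roughness,
rugosity, fluency) are computed on the filtered signal while the spectral
features (entropy, mean frequency, band energies) use the raw segment.  A
`literal_filtering` flag computes everything on the filtered signal.
Spectral features require ≥ 4 s of signal so each 0.5 Hz band spans at
least two periodogram bins; shorter segments yield undefined-feature
markers (NaN), as do zero-variance signals for the Hjorth and spectral
quantities.

## Statistical comparison

Each outcome is analysed per task with

    value ~ condition + (1 | participant)

fitted by REML (statsmodels `MixedLM`), condition categorical with "none"
as reference.  Repetitions within a participant × task × condition cell are
averaged before fitting (a switch keeps repetition-level rows).  The main
effect of condition is tested with a Wald F on the condition terms against
`F(k−1, n − g − (k−1))` — the containment denominator degrees of freedom,
which for the balanced one-row-per-cell design reduces to the exact
`(g−1)(k−1)`-df repeated-measures F.  This default was chosen over the
asymptotic likelihood-ratio chi-square (available as `method="lrt"`)
because the chi-square reference is anti-conservative at nine participants,
while the containment-df F is exactly calibrated there; the type-I error
simulations in the test suite check the 5% level against a [0.03, 0.07]
band over 1,000 null cohorts.  Post hoc all-pairs contrasts use the
studentized-range (Tukey) distribution with the same denominator df on the
model's fixed effects; adjusted p-values are clipped to be at least the
unadjusted ones.  No multiplicity correction is applied across the
task × outcome families, matching the study design.  Outcomes with no
within-participant variability (e.g., pause counts on single-stroke tasks)
short-circuit to a degenerate closed-form fit with undefined test
statistics rather than a spurious model.

## Synthetic data generator

The generator defines the conditions under which the pipeline is validated:

- **Tasks.** Rectangle (100 × 50-proportioned closed stroke, or 4 segments),
  Archimedean spiral `r = bθ` (3 turns), 10-vertex alternating-radius star,
  a prolate-cycloid loop chain for cursive "elelelel", and a multi-word
  "sentence" of smooth pseudo-random strokes separated by stylus lifts
  (5 words; 2+ strokes guarantee pauses).  Geometry is schematic: the
  downstream metrics depend on timing and stroke structure, not on
  glyph-accurate shapes.
- **Pen tremor.** An additive sinusoid applied normal to the local path
  tangent, default 6.5 Hz (the ~4–6 Hz Parkinsonian rest-tremor band
  shifted up ~1.5 Hz, as action tremor presents), default amplitude 4 px.
  Amplitude 0 returns the ideal path exactly.
- **Sampling.** Constant-speed traversal (150 px/s default) sampled at
  142 Hz with Gaussian inter-sample jitter (default SD 0.5 ms), clamped to
  keep timestamps increasing; stylus lifts of 0.5 s between strokes, with
  hover (pen-up) samples inside each lift.
- **Accelerometry.** 128 Hz; voluntary movement as a sum of three sub-2 Hz
  sinusoids (0.05 g), the tremor sinusoid distributed across axes with
  fixed unit-norm weights (default 0.15 g), white noise (0.03 g), and clap
  bursts — square-envelope alternating-sign samples whose vector power is
  at least the configured clap power (> 0.17 g²) for the whole burst
  (≥ 110 samples), inserted before the task onset.
- **Cohort structure.** 9 participants × 5 tasks × 3 conditions (one
  analysed repetition per cell, 135 recordings), participant random
  intercepts on tremor amplitude (N(0, 1 px)), repetition noise (0.5 px),
  and per-condition multiplicative amplitude effects defaulting to 1.0 —
  the null, matching the study's null result.  Ground-truth parameters are
  written alongside for recovery tests.
- **Outcome-level simulator.** For statistical calibration, trial tables
  are also simulated directly as `y = baseline + effect + intercept +
  noise` (intercept SD 2, residual SD 1, effects in residual-SD units), so
  type-I error, power, and variance recovery can be measured with thousands
  of replicates.

What the generator does **not** emulate: glyph-realistic handwriting,
biomechanical arm dynamics, the device's 205 Hz actuator waveform and
500 ms on/off duty cycle (no mechanism linking them to pen kinematics is
established; vibration enters only as an outcome-effect multiplier),
pressure/tilt channels, sensor-orientation fusion, or gravity offsets
(streams arrive axis-resolved and high-pass-equivalent).  Passing tests
therefore demonstrate correctness of the computation and calibration of
the inference under the assumed signal structure — not hardware-level
fidelity.

## Problem sizes and determinism

All generators are pure functions of (spec, seed); the pipeline rerun with
a fixed seed reproduces every table byte-for-byte, and each table carries a
hash of the configuration so tables from different configurations cannot be
mixed in the analysis stage.  The validation suite uses: 60 s sinusoids for
filter gains; 12 constructed traces for metric exactness plus a 1,000-series
brute-force peak comparison; 100 synthetic streams for clap sensitivity;
300 streams for spectral band recovery; 1,000 null cohorts (9 × 3) for
type-I error, 200 replicates per effect size for power, and 100 cohorts of
50 participants for variance recovery — sizes at which the binomial noise
on the measured rates is well inside the asserted bands.

## Known limitations

- Hjorth and band-energy magnitudes depend on windowing/detrending
  conventions; published values from other toolchains are not comparable
  without their exact preprocessing.
- The pause-time and pause-count outcomes are degenerate on single-stroke
  tasks (identically zero), and the analysis reports them as such.
- The no-threshold peak rule is sensitive to any residual ripple; compare
  peak counts only within a fixed preprocessing configuration.
- The condition-effect mechanism in the simulator is a testing device for
  the inference chain, not a claim about how vibration affects tremor.
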