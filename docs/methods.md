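# Methods

This note documents the models behind `keykin`, the parameter choices that
matter, and what the synthetic world does and does not establish.

## 1. Sensor model

The acquisition chain is modeled per key as

    count(t) = neutral + (bottom − neutral)·x(t)/D + δ(x) + ε(t),

rounded to an integer in [0, 4095] (12-bit ADC), where `x` is key depth in
mm (0 at rest, downward positive), `D` the calibrated key travel (default
10 mm), `neutral`/`bottom` the calibration counts, `δ` a smooth systematic
distortion and `ε` additive ground noise. Position is recovered by the
inverse linear map and reported on a 0.01 mm grid. Default imperfections
follow the bench figures of the reference hardware class:

| parameter | default | meaning |
|---|---|---|
| `ground_noise_amplitude` | 0.001 | peak-to-peak static noise as a fraction of the count range; drawn uniform, so the QC ratio (max−min)/range recovers it directly |
| `linearity_error_amplitude` | 0.024 | systematic distortion as the *recovered* linearity-error fraction |
| `linearity_spread_amplitude` | 0 | optional random per-sample spread (the systematic/random split of real sensors is unknown, so both knobs exist) |
| `quantization_step_mm` | 0.01 | position reporting resolution |
| `sampling_jitter_sd_ms` | 0.00808 | SD of the sampling interval |
| `adjacent_key_skew_ms` | 0.00596 | fixed per-key acquisition offset; recorded but ignored downstream (≪ 1 ms) |
| `clock_scale_error` | 4.16e−7 | relative clock-rate error |

The systematic distortion is a half-sine in depth, `δ(x) = A·sin(πx/D)`,
the simplest smooth zero-at-the-ends shape. `A` is scaled by the mean
absolute residual of a unit half-sine about its least-squares line
(≈ 0.268), so the staircase QC — fit counts~depth on a 0–10 mm, 1 mm
sweep, mean |residual| / count range — returns approximately the configured
fraction (on the 11-point grid it returns ~1.14× the continuous value,
comfortably inside the factor-2 acceptance band).

## 2. Filtering and differentiation

Position is low-pass filtered with a second-order Butterworth at 20 Hz, the
standard preprocessing for key-position data. We apply it forward–backward
(zero phase) so event timing is not biased by group delay; this doubles the
effective magnitude order. **Caveat measured here:** a 20 Hz cutoff
attenuates the peak velocity of a 50 ms minimum-jerk descent by ~18% and
adds ~0.18 mm of overshoot ringing at the dwell corners. Velocity
*magnitudes* from filtered fast strokes are therefore systematically low
(a common multiplicative bias largely removed by the z-scoring in the
regression stage, but fatal for absolute round-trip checks). The pipeline
exposes the filter as a skippable stage (`lowpass_hz=None`); accuracy tests
and the synthetic-cohort analyses run unfiltered, which is appropriate
because quantization noise at 0.01 mm is far below the segmentation
thresholds. Velocity is obtained by central differences (`np.gradient`),
exact for locally quadratic trajectories.

## 3. Event segmentation

Four events per cycle: onset, bottom arrival, release, offset. Detection is
two-stage:

* **Coarse:** excursions above `onset_frac`·D (default 2%, i.e. 0.2 mm),
  with hysteresis at half that threshold on the way out to suppress chatter;
  a dwell band at `bottom_frac` (default 95%) of the *stroke's own* maximum
  depth, so shallow strokes still get a dwell interval and a defined
  depression ratio.
* **Velocity refinement:** each boundary is walked to where |v| first falls
  below `vel_frac` (default 1%) of the stroke's peak speed (floor 2 mm/s).

The refinement exists because smooth strokes approach rest and bed very
gently: a pure 95% position band is crossed ~9 ms before the true bed
contact on a 50 ms minimum-jerk descent, and a 2% onset threshold ~6 ms
after true movement onset. The velocity criterion lands within ~1–2 ms of
the analytic junctions at 1 kHz, which is what makes event-derived durations
(dwell, peak-to-bottom, release-to-peak) accurate to ~3 ms through the full
quantized chain. Strokes cut by the trace boundary are flagged `truncated`
and excluded from feature statistics. Peak-velocity *times* are refined to
sub-sample resolution by the vertex of a parabola fitted over ±3 samples
around the argmax — velocity is flat at its extremum, so the raw argmax
wanders by a few ms under quantization noise while the parabola vertex does
not.

## 4. Features and metrics — conventions chosen here

Definitions left open by the measurement tradition, decided and config-exposed:

* **max_depth** is the excursion relative to the position at onset (a
  moving *distance*), making all six features invariant under a constant
  position offset.
* **IOI** uses key-motion *onsets* (they exist even for strokes that never
  reach the bed); a chord's keypress time is the mean of its two key onsets
  (`earliest` available); the trial value is the *mean* of successive
  differences.
* **Loudness balance** is the mean *absolute* within-chord difference in
  peak descending velocity, so it reads as an error magnitude (smaller =
  better); a signed mean is available.
* Chord pairing is greedy by maximal overlap of the [onset, release]
  depression intervals; orphans are reported and excluded.
* Inter-strike statistics use the sample SD (n−1) and require ≥ 2 complete
  strokes.
* Cohort predictors are taken from the fastest-tempo trial (the maximal
  performance probe); the IOI outcome from the same trial, loudness balance
  from the paced trial.

## 5. Skill regression

All predictors *and* outcomes are z-scored (n−1 SD), so coefficients are
fully standardized weights; inverse transforms are retained. Hyperparameters
are selected by 5-fold cross-validated MSE over a log-spaced α grid
(10⁻³…10⁰·⁵, 20 points) × L1-ratio grid {0.1, …, 1.0}, exact ties broken
toward larger α. R² is reported in-sample (fitted vs observed), with the
cross-validated R² (1 − CV-MSE/Var y) alongside under its own name — the
two differ by 0.05–0.15 at n = 49 and conflating them overstates fit
quality. Note that hyperparameter *selection* depends on fold assignment
and hence on row order; the refit at fixed hyperparameters does not (and is
invariant to predictor permutation, which only permutes coefficients).

## 6. The synthetic world

**Strokes** are minimum-jerk by default — `x(s) = D(10s³ − 15s⁴ + 6s⁵)`,
peak velocity 1.875·D/T at midphase — the standard smooth-reach model, with
a half-cosine alternative (peak π·D/2T) to keep feature code shape-agnostic.
Dwell is exactly constant at depth; position and velocity are continuous at
junctions, and every stroke exposes closed-form event times and feature
values for oracle tests.

**Trials** alternate two major-third dyads (MIDI {60, 64} and {62, 65},
one white key apart) for 6 s. Fastest condition: 8 chord strikes/s
(IOI 125 ms) by default; paced: 100 bpm × 2 strikes/beat (IOI 300 ms).
Between-stroke variability: peak-velocity SD 5% (Gaussian, shared within a
chord), dwell SD 8 ms and ascent SD 4 ms (log-normal — strictly positive),
depth SD 0.15 mm (log-normal), chord-onset jitter 5 ms and within-chord
asynchrony 5 ms (Gaussian). The within-chord velocity difference is drawn
`N(0, δ√(π/2))` so its mean absolute value equals the programmed balance
error δ (default 30 mm/s). If a drawn stroke's full cycle would collide with
the key's next strike, its dwell is shortened so the key rests ≥ 5 ms at top
between strokes — a pianist pressed for time releases early — and the
recorded ground truth reflects the shortened dwell; only a gap too small for
descent + ascent alone raises an infeasible-rate error. These variability
levels are order-of-magnitude choices — the real inter-strike distributions of expert pianists are not
published — selected to be large enough to exercise the statistics and
small enough to keep strokes well separated at the fastest rate.

**Cohorts** draw five latent traits per pianist (standard normal, truncated
at ±2.5): dwell level, ascent duration, peak descending velocity, velocity
variability, dwell variability. Programmed IOI rises with the dwell and
ascent traits and falls with the velocity trait; programmed balance error
rises with velocity variability and ascending velocity (short ascents) and
falls with dwell variability. One known confound is deliberate: ascent
duration drives both `release_to_peak` (mean) and `peak_asc_vel`
(inversely), as it must for any single-parameter ascent shape, so those two
predictors are collinear in trace-level cohorts and the net may split or
pick either — the table-level generator (next) is the clean testbed.

**Planted tables** (`planted_cohort_table`) skip trajectory synthesis: 12
i.i.d. standard-normal predictors, outcomes `y = Xβ + ε` with three planted
effects per outcome — IOI: −`peak_des_vel_mean`, +`release_to_peak_mean`,
+`depression_ratio_mean`; balance: +`peak_des_vel_sd`, +`peak_asc_vel_mean`,
−`depression_ratio_sd` — with *equal* magnitudes scaled so the population
R² is 0.85. Equal weights are the agnostic choice: published coefficient
magnitudes are fitted values on unavailable data, not a generative model,
and planting very small weights would turn sign-recovery tests into tests
of sample size rather than of the fitting code.

**What a green test establishes.** The generators share no code with the
measurement path (closed forms vs filtering/differencing/thresholding), so
round-trip agreement is informative about the measurement code. They do not
emulate: finger or hammer biomechanics, touch force, acoustic loudness,
partial strokes/missed notes, drift or temperature effects in the sensor,
or realistic inter-feature correlation structure beyond the planted traits.
Conclusions about *human* skill transfer only insofar as real touches
resemble smooth single-peak strokes with independent stroke-level noise.

## 7. Numerical details and degenerate inputs

* All randomness flows through `numpy.random.default_rng` seeded per run;
  identical seeds give byte-identical outputs (tested).
* Segmentation is idempotent and time-shift equivariant; events are
  validated to satisfy onset < bottom ≤ release < offset, and excursions
  that cannot satisfy it (e.g. chatter, cycles missing their descent) are
  dropped rather than fabricated.
* Zero-variance columns abort standardization with the column named;
  identical staircase depths, non-monotonic clocks, < 2 strokes, < 3 chord
  strikes and empty chord pairings raise typed errors rather than NaNs.
* Elastic-net coordinate descent runs at tol 1e−6 (CV) / 1e−8 (final refit)
  with warm starts along each α path; α = 0 and L1 ratio = 0 are allowed
  (verified against exact least squares and closed-form ridge).
* CSV event times are read with pandas' `round_trip` parser so serialization
  is exact to the last ulp.

## 8. Known limitations

* The 20 Hz filter bias on fast-stroke velocities (§2) means absolute
  velocity features from filtered data are comparable *within* a pipeline
  configuration, not across configurations.
* Event refinement assumes a single velocity peak per descent/ascent;
  double-contact touches (key bounce) would need a richer event model.
* The trace-level cohort induces qualitative, not calibrated, effect sizes;
  quantitative recovery claims are made only on the table-level generator.
* `pair_chords` is greedy; pathological overlap patterns (massively
  asynchronous playing) could pair suboptimally, though orphan reporting
  makes this visible.
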