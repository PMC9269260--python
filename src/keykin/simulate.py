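"""Synthetic keystrokes, trials and cohorts with known ground truth.

No public recording of the 49-pianist chord-trill dataset exists, so every
stage of the pipeline is exercised against simulated data whose ground truth
is known by construction:

* :func:`analytic_stroke` — one keystroke as a closed-form trajectory
  (minimum-jerk by default, half-cosine as an alternative) with exact event
  times and exact feature values, so feature code can be checked against
  algebra rather than against itself.
* :func:`simulate_trial` — a 6 s chord-trill trial: two two-key chords
  (major-third dyads) alternating at a programmed rate, with controllable
  between-stroke variability, chord asynchrony and loudness-balance error.
* :func:`simulate_cohort` — a cohort of pianists whose latent "skill" traits
  induce the qualitative feature-outcome associations seen in expert data
  (faster players show shorter key-depression and earlier key lift; less
  balanced players show larger stroke-to-stroke velocity variability).
* :func:`planted_cohort_table` — a cohort *table* with exactly planted
  linear effects and a chosen true R-squared, for regression recovery and
  null-calibration experiments at Monte-Carlo scale.

Randomness: every generator takes a seed (or Generator); positive-valued
quantities (durations, depths) are drawn log-normally, unbounded ones
normally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InfeasibleRateError
from .features import (
    FEATURE_NAMES,
    OUTCOME_COLUMNS,
    PREDICTOR_COLUMNS,
    StrokeFeatures,
)
from .segmentation import StrokeEvent
from .trace import KeyTrace

#: default chord keys: two major-third dyads one white key apart
#: (index+ring vs middle+little finger in the original task)
CHORD_A = (60, 64)
CHORD_B = (62, 65)

#: peak-velocity coefficient per trajectory shape: v_peak = coef * depth / T
SHAPE_COEF = {"min_jerk": 1.875, "half_cosine": math.pi / 2.0}


def _minjerk_pos(s: np.ndarray) -> np.ndarray:
    return 10.0 * s**3 - 15.0 * s**4 + 6.0 * s**5


def _minjerk_vel(s: np.ndarray) -> np.ndarray:
    return 30.0 * s**2 - 60.0 * s**3 + 30.0 * s**4


def _halfcos_pos(s: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(np.pi * s))


def _halfcos_vel(s: np.ndarray) -> np.ndarray:
    return 0.5 * np.pi * np.sin(np.pi * s)


_SHAPES = {"min_jerk": (_minjerk_pos, _minjerk_vel),
           "half_cosine": (_halfcos_pos, _halfcos_vel)}


@dataclass(frozen=True)
class StrokeSpec:
    """Parametric description of one keystroke cycle."""

    descent_ms: float
    dwell_ms: float
    ascent_ms: float
    depth_mm: float = 10.0
    shape: str = "min_jerk"
    onset_ms: float = 0.0

    def __post_init__(self):
        if min(self.descent_ms, self.dwell_ms, self.ascent_ms) <= 0:
            raise ConfigurationError("all stroke durations must be > 0")
        if not (0.0 < self.depth_mm <= 12.0):
            raise ConfigurationError(f"depth {self.depth_mm} mm outside (0, 12]")
        if self.shape not in _SHAPES:
            raise ConfigurationError(
                f"unknown trajectory shape {self.shape!r}; choose from {sorted(_SHAPES)}")

    @property
    def cycle_ms(self) -> float:
        return self.descent_ms + self.dwell_ms + self.ascent_ms


class AnalyticStroke:
    """Closed-form trajectory of one keystroke.

    Descent and ascent follow the chosen shape; the dwell is exactly
    constant at ``depth_mm``. Position and velocity are continuous at the
    junctions (both shapes have zero end-point velocity).
    """

    def __init__(self, spec: StrokeSpec):
        self.spec = spec
        self._pos, self._vel = _SHAPES[spec.shape]

    def x_at(self, t_ms) -> np.ndarray:
        """Position (mm) at absolute time(s) ``t_ms``."""
        sp = self.spec
        u = np.asarray(t_ms, dtype=float) - sp.onset_ms
        x = np.zeros_like(u)
        m = (u >= 0) & (u < sp.descent_ms)
        x[m] = sp.depth_mm * self._pos(u[m] / sp.descent_ms)
        m = (u >= sp.descent_ms) & (u < sp.descent_ms + sp.dwell_ms)
        x[m] = sp.depth_mm
        m = (u >= sp.descent_ms + sp.dwell_ms) & (u < sp.cycle_ms)
        x[m] = sp.depth_mm * self._pos(1.0 - (u[m] - sp.descent_ms - sp.dwell_ms)
                                       / sp.ascent_ms)
        return x

    def v_at(self, t_ms) -> np.ndarray:
        """Velocity (mm/s, downward positive) at absolute time(s) ``t_ms``."""
        sp = self.spec
        u = np.asarray(t_ms, dtype=float) - sp.onset_ms
        v = np.zeros_like(u)
        m = (u >= 0) & (u < sp.descent_ms)
        v[m] = sp.depth_mm / sp.descent_ms * self._vel(u[m] / sp.descent_ms) * 1000.0
        m = (u >= sp.descent_ms + sp.dwell_ms) & (u < sp.cycle_ms)
        v[m] = -sp.depth_mm / sp.ascent_ms * self._vel(
            1.0 - (u[m] - sp.descent_ms - sp.dwell_ms) / sp.ascent_ms) * 1000.0
        return v

    @property
    def events(self) -> StrokeEvent:
        """Exact junction times of the cycle."""
        sp = self.spec
        return StrokeEvent(sp.onset_ms,
                           sp.onset_ms + sp.descent_ms,
                           sp.onset_ms + sp.descent_ms + sp.dwell_ms,
                           sp.onset_ms + sp.cycle_ms)

    @property
    def true_features(self) -> StrokeFeatures:
        """Closed-form feature values (peak velocity = coef * depth / T at
        the phase midpoint for both shapes)."""
        sp = self.spec
        coef = SHAPE_COEF[sp.shape]
        return StrokeFeatures(
            peak_des_vel=coef * sp.depth_mm / sp.descent_ms * 1000.0,
            peak_asc_vel=coef * sp.depth_mm / sp.ascent_ms * 1000.0,
            max_depth=sp.depth_mm,
            peak_to_bottom=sp.descent_ms / 2.0,
            release_to_peak=sp.ascent_ms / 2.0,
            depression_ratio=sp.dwell_ms / sp.cycle_ms,
        )

    def sample(self, fs_hz: float = 1000.0, pad_ms: float = 50.0,
               key_id: int = 60) -> KeyTrace:
        """Sample the stroke on a uniform grid with rest padding each side."""
        sp = self.spec
        t = np.arange(sp.onset_ms - pad_ms, sp.onset_ms + sp.cycle_ms + pad_ms,
                      1000.0 / fs_hz)
        tr = KeyTrace(key_id, t, self.x_at(t), depth_range_mm=max(10.0, sp.depth_mm))
        return tr.with_(v=self.v_at(t))


def analytic_stroke(spec: StrokeSpec) -> AnalyticStroke:
    """Closed-form x(t), v(t) for one keystroke cycle."""
    return AnalyticStroke(spec)


# ---------------------------------------------------------------------------
# trials


@dataclass
class PianistSpec:
    """One pianist's programmed touch parameters.

    ``peak_des_vel`` sets the mean target peak descending velocity; the
    descent duration follows from it and the trajectory shape. Between-stroke
    variability is controlled by the ``*_sd`` fields; ``balance_error_mm_s``
    is the expected mean |velocity difference| within a chord (the planted
    loudness-balance error); ``chord_async_sd_ms`` is the within-chord onset
    asynchrony.
    """

    peak_des_vel: float = 375.0          # mm/s
    dwell_fastest_ms: float = 55.0
    dwell_paced_ms: float = 150.0
    ascent_ms: float = 40.0
    depth_mm: float = 10.0
    shape: str = "min_jerk"
    rate_fastest_hz: float = 8.0         # chord strikes per second, fastest trial
    paced_bpm: float = 100.0
    strikes_per_beat: float = 2.0        # paced chord rate = bpm/60 * this
    vel_sd_frac: float = 0.05            # between-stroke SD of peak velocity
    dwell_sd_ms: float = 8.0
    ascent_sd_ms: float = 4.0
    depth_sd_mm: float = 0.15
    timing_jitter_sd_ms: float = 5.0     # chord-onset jitter
    chord_async_sd_ms: float = 5.0       # within-chord key asynchrony
    balance_error_mm_s: float = 30.0     # expected mean |dv| within chords

    def __post_init__(self):
        if self.rate_fastest_hz <= 0 or self.paced_bpm <= 0:
            raise ConfigurationError("strike rates must be > 0")
        for name in ("vel_sd_frac", "dwell_sd_ms", "ascent_sd_ms", "depth_sd_mm",
                     "timing_jitter_sd_ms", "chord_async_sd_ms", "balance_error_mm_s"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def rate_hz(self, condition: str) -> float:
        if condition == "fastest":
            return self.rate_fastest_hz
        if condition == "paced":
            return self.paced_bpm / 60.0 * self.strikes_per_beat
        raise ConfigurationError(f"unknown condition {condition!r}")

    def dwell_ms(self, condition: str) -> float:
        return self.dwell_fastest_ms if condition == "fastest" else self.dwell_paced_ms


@dataclass
class Trial:
    """One simulated trial with its full ground truth."""

    condition: str
    traces: dict[int, KeyTrace]
    true_events: dict[int, list[StrokeEvent]]
    true_features: dict[int, list[StrokeFeatures]]
    chords: tuple[tuple[int, int], tuple[int, int]]
    chord_onsets_ms: np.ndarray          # scheduled chord times incl. jitter
    programmed_ioi_ms: float
    programmed_balance_mm_s: float


def _lognormal(rng, mean, sd, size=None):
    """Log-normal with the given arithmetic mean and SD (moment-matched)."""
    if sd == 0:
        return np.full(size, float(mean)) if size is not None else float(mean)
    s2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2.0
    return rng.lognormal(mu, math.sqrt(s2), size=size)


def simulate_trial(p: PianistSpec, condition: str, duration_s: float = 6.0,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   chords: tuple = (CHORD_A, CHORD_B),
                   fs_hz: float = 1000.0) -> Trial:
    """Simulate one chord-trill trial for one pianist.

    Chord A and chord B alternate at the condition's programmed rate for
    ``duration_s`` seconds; each chord is two keys struck near-simultaneously.
    Per-stroke trajectory parameters are drawn with the spec's between-stroke
    SDs; the two keys of a chord share a common stroke-level velocity
    deviation plus half of an antisymmetric balance error, so the programmed
    within-chord velocity difference has mean absolute value
    ``balance_error_mm_s`` exactly.

    Returns analytic (noise-free) traces at ``fs_hz`` plus exact per-stroke
    events and features. Pass the result through :func:`keykin.sensor.sensorize`
    to add the acquisition chain.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    rate = p.rate_hz(condition)
    period = 1000.0 / rate
    coef = SHAPE_COEF[p.shape]

    # feasibility: each key strikes every other chord, so its mean cycle plus
    # modest stochastic headroom must fit within two chord periods; an actual
    # collision between draws still raises below
    mean_cycle = (coef * p.depth_mm / p.peak_des_vel * 1000.0
                  + p.dwell_ms(condition) + p.ascent_ms)
    if mean_cycle * 1.15 + 20.0 > 2 * period:
        raise InfeasibleRateError(
            f"mean cycle of ~{mean_cycle:.0f} ms does not fit the per-key period "
            f"of {2 * period:.0f} ms at {rate:.2f} strikes/s")

    margin = 60.0  # ms of rest before the first chord
    # the last chord's full cycle (plus jitter headroom) must end inside the trace
    tail = mean_cycle + 30.0
    n_chords = max(int((duration_s * 1000.0 - margin - tail) // period) + 1, 1)
    onsets = margin + np.arange(n_chords) * period
    onsets = onsets + rng.normal(0.0, p.timing_jitter_sd_ms, size=n_chords)
    onsets = np.sort(onsets)

    key_strokes: dict[int, list[AnalyticStroke]] = {k: [] for pair in chords for k in pair}
    sigma_bal = p.balance_error_mm_s * math.sqrt(math.pi / 2.0)  # E|N(0,s)| = s*sqrt(2/pi)
    for i, t0 in enumerate(onsets):
        pair = chords[i % 2]
        eps_common = rng.normal(0.0, p.vel_sd_frac)
        dv = rng.normal(0.0, sigma_bal)
        asym = rng.normal(0.0, p.chord_async_sd_ms)
        for j, key in enumerate(pair):
            vel = p.peak_des_vel * (1.0 + eps_common) + (0.5 - j) * 2 * dv / 2.0
            vel = max(vel, 50.0)
            depth = float(_lognormal(rng, p.depth_mm, p.depth_sd_mm))
            depth = min(depth, 12.0)
            spec = StrokeSpec(
                descent_ms=coef * depth / vel * 1000.0,
                dwell_ms=float(_lognormal(rng, p.dwell_ms(condition), p.dwell_sd_ms)),
                ascent_ms=float(_lognormal(rng, p.ascent_ms, p.ascent_sd_ms)),
                depth_mm=depth, shape=p.shape,
                onset_ms=float(t0 + (j - 0.5) * asym),
            )
            key_strokes[key].append(spec)

    n = int(round(duration_s * 1000.0 / (1000.0 / fs_hz)))
    t = np.arange(n) * (1000.0 / fs_hz)
    traces, true_events, true_features = {}, {}, {}
    min_gap = 5.0  # ms of rest the key must spend at top between strokes
    for key, specs in key_strokes.items():
        specs.sort(key=lambda s: s.onset_ms)
        # a pianist pressed for time releases early: shorten the dwell of a
        # stroke whose full cycle would collide with the next strike
        for i in range(len(specs) - 1):
            s, nxt = specs[i], specs[i + 1]
            room = nxt.onset_ms - min_gap - s.onset_ms - s.descent_ms - s.ascent_ms
            if room <= 1.0:
                raise InfeasibleRateError(
                    f"key {key}: descent+ascent alone exceed the gap before "
                    f"{nxt.onset_ms:.0f} ms; lower the rate or the jitter")
            if s.dwell_ms > room:
                specs[i] = replace(s, dwell_ms=room)
        strokes = [AnalyticStroke(s) for s in specs]
        x = np.zeros(n)
        for s in strokes:
            i0 = max(int(np.ceil(s.spec.onset_ms * fs_hz / 1000.0)), 0)
            i1 = min(int(np.floor((s.spec.onset_ms + s.spec.cycle_ms) * fs_hz / 1000.0)) + 1, n)
            x[i0:i1] = s.x_at(t[i0:i1])
        traces[key] = KeyTrace(key, t.copy(), x, depth_range_mm=10.0)
        true_events[key] = [s.events for s in strokes]
        true_features[key] = [s.true_features for s in strokes]

    return Trial(condition=condition, traces=traces, true_events=true_events,
                 true_features=true_features, chords=chords,
                 chord_onsets_ms=onsets, programmed_ioi_ms=period,
                 programmed_balance_mm_s=p.balance_error_mm_s)


# ---------------------------------------------------------------------------
# cohorts

#: sign structure of the planted effects, mirroring the associations reported
#: for expert cohorts: faster players (small IOI) hit harder, lift earlier and
#: dwell proportionally less; well-balanced players (small balance error) have
#: consistent strike velocity / dwell and slower key lifts.
PLANTED_SIGNS = {
    "fastest_ioi": {"peak_des_vel_mean": -1, "release_to_peak_mean": +1,
                    "depression_ratio_mean": +1},
    "loudness_balance": {"peak_des_vel_sd": +1, "peak_asc_vel_mean": +1,
                         "depression_ratio_sd": -1},
}


@dataclass
class CohortSpec:
    """A cohort of pianists with latent skill traits.

    Five independent standard-normal traits per pianist (truncated at +-2.5
    SD) drive the programmed parameters:

    z1 dwell/depression-ratio level, z2 ascent duration (key-lift timing and,
    inversely, ascending velocity), z3 peak descending velocity, z4
    between-stroke velocity variability, z5 between-stroke dwell variability.

    The programmed fastest IOI rises with z1 and z2 and falls with z3; the
    programmed balance error rises with z4 and the ascending velocity (-z2)
    and falls with z5 — the qualitative structure recovered by the
    regression stage.
    """

    n_pianists: int = 49
    seed: int = 0
    base: PianistSpec = field(default_factory=PianistSpec)
    # trait -> parameter scales
    dwell_scale_ms: float = 8.0
    ascent_scale_ms: float = 6.0
    vel_scale_mm_s: float = 35.0
    velsd_scale: float = 0.02
    dwellsd_scale_ms: float = 3.0
    # trait -> outcome weights
    ioi_base_ms: float = 128.0
    ioi_weights: tuple = (8.0, 8.0, 8.0)   # z1, z2, -z3
    ioi_noise_ms: float = 4.0
    ioi_min_ms: float = 110.0
    balance_base_mm_s: float = 30.0
    balance_weights: tuple = (8.0, 5.0, 5.0)  # z4, -z2, -z5
    balance_noise_mm_s: float = 3.0
    balance_min_mm_s: float = 5.0

    def __post_init__(self):
        if self.n_pianists < len(PREDICTOR_COLUMNS) + 2:
            raise ConfigurationError(
                f"need >= {len(PREDICTOR_COLUMNS) + 2} pianists for downstream fitting")


@dataclass
class PianistRecord:
    pianist_id: int
    spec: PianistSpec
    traits: dict[str, float]
    trials: dict[str, Trial]
    stream_seeds: dict[str, int] | None = None


def simulate_cohort(c: CohortSpec, duration_s: float = 6.0,
                    noise_spec=None) -> list[PianistRecord]:
    """Simulate every pianist's fastest and paced trials.

    When ``noise_spec`` (a :class:`keykin.sensor.SensorNoiseSpec`) is given,
    each trial's traces are replaced by the sensorized-then-reconverted
    versions, i.e. the cohort is observed through the simulated acquisition
    chain instead of directly.
    """
    master = np.random.default_rng(c.seed)
    records = []
    for pid in range(c.n_pianists):
        rng = np.random.default_rng(master.integers(2**31))
        z = np.clip(rng.standard_normal(5), -2.5, 2.5)
        z1, z2, z3, z4, z5 = z

        ioi = max(c.ioi_base_ms + c.ioi_weights[0] * z1 + c.ioi_weights[1] * z2
                  - c.ioi_weights[2] * z3 + rng.normal(0, c.ioi_noise_ms), c.ioi_min_ms)
        bal = max(c.balance_base_mm_s + c.balance_weights[0] * z4
                  - c.balance_weights[1] * z2 - c.balance_weights[2] * z5
                  + rng.normal(0, c.balance_noise_mm_s), c.balance_min_mm_s)

        spec = replace(
            c.base,
            peak_des_vel=c.base.peak_des_vel + c.vel_scale_mm_s * z3,
            dwell_fastest_ms=c.base.dwell_fastest_ms + c.dwell_scale_ms * z1,
            dwell_paced_ms=c.base.dwell_paced_ms + 2 * c.dwell_scale_ms * z1,
            ascent_ms=c.base.ascent_ms + c.ascent_scale_ms * z2,
            vel_sd_frac=max(c.base.vel_sd_frac + c.velsd_scale * z4, 0.005),
            dwell_sd_ms=max(c.base.dwell_sd_ms + c.dwellsd_scale_ms * z5, 1.0),
            rate_fastest_hz=1000.0 / ioi,
            balance_error_mm_s=bal,
        )
        trials = {cond: simulate_trial(spec, cond, duration_s=duration_s, rng=rng)
                  for cond in ("fastest", "paced")}
        if noise_spec is not None:
            from .sensor import CalibrationTable, convert_counts_to_position, sensorize
            cal = CalibrationTable.uniform([k for pair in (CHORD_A, CHORD_B) for k in pair])
            for cond, trial in trials.items():
                stream = sensorize(trial.traces, cal, noise_spec,
                                   seed=int(rng.integers(2**31)))
                trial.traces = convert_counts_to_position(stream, cal)
        records.append(PianistRecord(
            pianist_id=pid, spec=spec,
            traits={f"z{i + 1}": float(v) for i, v in enumerate(z)},
            trials=trials))
    return records


def planted_cohort_table(n: int = 49, r2: float = 0.85, seed: int = 0,
                         signs: dict | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort table with exactly planted linear effects.

    Draws the 12 predictors i.i.d. standard normal and builds each outcome as
    y = X beta + noise with the sign structure of :data:`PLANTED_SIGNS`
    (three effects per outcome), equal |beta| across an outcome's planted
    effects, scaled so the population R-squared equals ``r2``. ``r2 = 0``
    plants nothing (pure noise outcomes) for null calibration.

    Returns
    -------
    (table, beta) : DataFrame, DataFrame
        ``table``: one row per pianist, 12 predictor columns + 2 outcomes;
        ``beta``: true coefficients, predictors x outcomes.
    """
    if not (0.0 <= r2 < 1.0):
        raise ConfigurationError(f"r2 must lie in [0, 1), got {r2}")
    signs = PLANTED_SIGNS if signs is None else signs
    unknown = {p for eff in signs.values() for p in eff} - set(PREDICTOR_COLUMNS)
    if unknown:
        raise ConfigurationError(f"effect map references unknown predictors: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, len(PREDICTOR_COLUMNS))),
                     columns=list(PREDICTOR_COLUMNS))
    beta = pd.DataFrame(0.0, index=list(PREDICTOR_COLUMNS), columns=list(OUTCOME_COLUMNS))
    table = X.copy()
    for outcome in OUTCOME_COLUMNS:
        effects = signs.get(outcome, {})
        if r2 > 0 and effects:
            b = math.sqrt(r2 / len(effects))
            for pred, sign in effects.items():
                beta.loc[pred, outcome] = sign * b
        noise_sd = math.sqrt(1.0 - r2) if effects and r2 > 0 else 1.0
        table[outcome] = (X.to_numpy() @ beta[outcome].to_numpy()
                          + rng.normal(0.0, noise_sd, size=n))
    table.insert(0, "pianist_id", np.arange(n))
    return table, beta
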