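"""Per-stroke kinematic features and trial-level performance metrics.

Six features describe one keystroke cycle:

==================  =====  ====================================================
peak_des_vel        mm/s   peak downward speed during key depression
peak_asc_vel        mm/s   peak upward speed during key release
max_depth           mm     maximum key-moving distance (excursion relative to
                           the position at onset)
peak_to_bottom      ms     time from the descending-velocity peak to bed arrival
release_to_peak     ms     time from leaving the bed to the ascending-velocity peak
depression_ratio    --     fraction of the cycle spent on the key bed
==================  =====  ====================================================

Two trial-level metrics index performance: the mean inter-keystroke interval
of the fastest-tempo trial (maximum playing speed) and the loudness balance
of the paced trial — the mean absolute difference in peak descending
velocity between the two keys of a chord, a proxy for the loudness match of
the two tones since descending key velocity determines tone loudness.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import (
    InsufficientDataError,
    InsufficientStrokesError,
    InvariantViolationError,
)
from .segmentation import StrokeEvent
from .trace import KeyTrace

FEATURE_NAMES = ("peak_des_vel", "peak_asc_vel", "max_depth",
                 "peak_to_bottom", "release_to_peak", "depression_ratio")

#: the 12 cohort predictors: inter-strike mean and SD of each feature
PREDICTOR_COLUMNS = tuple(f"{f}_{s}" for f in FEATURE_NAMES for s in ("mean", "sd"))
OUTCOME_COLUMNS = ("fastest_ioi", "loudness_balance")


@dataclass(frozen=True)
class StrokeFeatures:
    peak_des_vel: float      # mm/s, positive magnitude
    peak_asc_vel: float      # mm/s, positive magnitude
    max_depth: float         # mm
    peak_to_bottom: float    # ms
    release_to_peak: float   # ms
    depression_ratio: float  # dimensionless, in (0, 1)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _peak_time(trace: KeyTrace, i_peak: int, lo: int, hi: int, half: int = 3) -> float:
    """Sub-sample peak time by a local parabola through the velocity samples.

    Velocity is flat around its extremum, so the raw argmax wanders by a few
    samples under quantization noise; the vertex of a quadratic fit over
    +-``half`` samples is far more stable. Falls back to the argmax sample
    when the window is degenerate or the fit is not concave.
    """
    a, b = max(lo, i_peak - half), min(hi, i_peak + half) + 1
    if b - a >= 3:
        tt = trace.t[a:b] - trace.t[i_peak]
        vv = np.abs(trace.v[a:b])
        c2, c1, _ = np.polyfit(tt, vv, 2)
        if c2 < 0:
            dt = -c1 / (2.0 * c2)
            if abs(dt) <= half * trace.dt_ms:
                return float(trace.t[i_peak] + dt)
    return float(trace.t[i_peak])


def _index(trace: KeyTrace, time_ms: float, what: str) -> int:
    i = int(np.searchsorted(trace.t, time_ms))
    if i >= trace.n or abs(trace.t[min(i, trace.n - 1)] - time_ms) > trace.dt_ms:
        raise InvariantViolationError(f"{what} at {time_ms} ms lies outside the trace")
    return i


def stroke_features(ev: StrokeEvent, trace: KeyTrace) -> StrokeFeatures:
    """Compute the six features of one stroke from its event times.

    Velocity must be populated. The descending peak is searched in
    [onset, bottom_arrival], the ascending peak in [release, offset]; both
    are reported as positive magnitudes (position is downward-positive).
    """
    if trace.v is None:
        raise InvariantViolationError("trace velocity not populated; differentiate first")
    i_on = _index(trace, ev.onset_ms, "onset")
    i_bot = _index(trace, ev.bottom_arrival_ms, "bottom_arrival")
    i_rel = _index(trace, ev.release_ms, "release")
    i_off = _index(trace, ev.offset_ms, "offset")
    if not (i_on < i_bot <= i_rel < i_off):
        raise InvariantViolationError("events out of order relative to the trace grid")

    v_des = trace.v[i_on:i_bot + 1]
    i_pk_des = i_on + int(np.argmax(v_des))
    v_asc = -trace.v[i_rel:i_off + 1]
    i_pk_asc = i_rel + int(np.argmax(v_asc))

    cycle = trace.t[i_off] - trace.t[i_on]
    t_pk_des = _peak_time(trace, i_pk_des, i_on, i_bot)
    t_pk_asc = _peak_time(trace, i_pk_asc, i_rel, i_off)
    return StrokeFeatures(
        peak_des_vel=float(v_des.max()),
        peak_asc_vel=float(v_asc.max()),
        max_depth=float(trace.x[i_on:i_off + 1].max() - trace.x[i_on]),
        peak_to_bottom=float(trace.t[i_bot] - t_pk_des),
        release_to_peak=float(t_pk_asc - trace.t[i_rel]),
        depression_ratio=float((trace.t[i_rel] - trace.t[i_bot]) / cycle),
    )


@dataclass
class TrialSummary:
    """Inter-strike mean and SD of each feature, plus the trial's metric."""

    condition: str                      # "fastest" | "paced"
    n_strokes: int
    means: dict[str, float]
    sds: dict[str, float]
    ioi_ms: float | None = None                 # fastest condition
    loudness_balance_mm_s: float | None = None  # paced condition

    def predictor_row(self) -> dict[str, float]:
        """The 12 predictor cells this trial contributes to a cohort table."""
        row = {f"{k}_mean": v for k, v in self.means.items()}
        row.update({f"{k}_sd": v for k, v in self.sds.items()})
        return row


def summarize_trial(strokes: list[StrokeFeatures], condition: str,
                    ioi_ms: float | None = None,
                    loudness_balance_mm_s: float | None = None) -> TrialSummary:
    """Inter-strike sample mean and SD (n-1 denominator) per feature."""
    if len(strokes) < 2:
        raise InsufficientStrokesError(
            f"need >= 2 complete strokes for inter-strike statistics, got {len(strokes)}")
    arr = {name: np.array([getattr(s, name) for s in strokes]) for name in FEATURE_NAMES}
    return TrialSummary(
        condition=condition,
        n_strokes=len(strokes),
        means={k: float(v.mean()) for k, v in arr.items()},
        sds={k: float(v.std(ddof=1)) for k, v in arr.items()},
        ioi_ms=ioi_ms,
        loudness_balance_mm_s=loudness_balance_mm_s,
    )


def pair_chords(events_a: list[StrokeEvent], events_b: list[StrokeEvent]
                ) -> tuple[list[tuple[StrokeEvent, StrokeEvent]], list[StrokeEvent]]:
    """Pair simultaneous strokes of a chord's two keys.

    Greedy matching by maximal overlap of the [onset, release] depression
    intervals; strokes that overlap nothing on the other key are reported as
    orphans and excluded from the balance metric.
    """
    candidates = []
    for i, ea in enumerate(events_a):
        for j, eb in enumerate(events_b):
            overlap = (min(ea.release_ms, eb.release_ms)
                       - max(ea.onset_ms, eb.onset_ms))
            if overlap > 0:
                candidates.append((overlap, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_a, used_b, pairs = set(), set(), []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((events_a[i], events_b[j]))
    pairs.sort(key=lambda p: p[0].onset_ms)
    orphans = [e for k, e in enumerate(events_a) if k not in used_a]
    orphans += [e for k, e in enumerate(events_b) if k not in used_b]
    return pairs, orphans


def chord_onsets(pairs: list[tuple[StrokeEvent, StrokeEvent]],
                 mode: str = "mean") -> np.ndarray:
    """One keypress time per chord: mean (default) or earliest of the two
    constituent key onsets."""
    if mode == "mean":
        out = [(a.onset_ms + b.onset_ms) / 2.0 for a, b in pairs]
    elif mode == "earliest":
        out = [min(a.onset_ms, b.onset_ms) for a, b in pairs]
    else:
        raise ValueError(f"unknown chord-onset mode {mode!r}")
    return np.sort(np.asarray(out))


def fastest_ioi(onsets_ms) -> float:
    """Mean inter-keystroke interval (ms) of the fastest-tempo trial.

    ``onsets_ms`` are the chord keypress times; at least 3 strikes are
    required for a meaningful mean of successive differences.
    """
    onsets = np.sort(np.asarray(onsets_ms, dtype=float))
    if onsets.size < 3:
        raise InsufficientDataError(
            f"need >= 3 chord strikes for an IOI estimate, got {onsets.size}")
    return float(np.mean(np.diff(onsets)))


def loudness_balance(paired_features: list[tuple[StrokeFeatures, StrokeFeatures]],
                     signed: bool = False) -> float:
    """Mean per-chord difference in peak descending velocity (mm/s).

    Absolute by default, so the number reads as an error magnitude (0 =
    perfectly matched loudness); ``signed=True`` averages raw differences
    instead.
    """
    if not paired_features:
        raise InsufficientDataError("no paired chords; cannot compute loudness balance")
    d = np.array([a.peak_des_vel - b.peak_des_vel for a, b in paired_features])
    return float(np.mean(d if signed else np.abs(d)))
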