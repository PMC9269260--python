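"""End-to-end orchestration: traces -> events -> features -> cohort table -> fits.

The measurement convention for the cohort table: the 12 predictors are the
inter-strike mean/SD of the six features pooled over the four keys of the
fastest-tempo trial (the maximal-performance probe); the fastest-tempo IOI
comes from that same trial and the loudness balance from the paced trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import regression
from .errors import InsufficientDataError
from .features import (
    OUTCOME_COLUMNS,
    PREDICTOR_COLUMNS,
    TrialSummary,
    chord_onsets,
    fastest_ioi,
    loudness_balance,
    pair_chords,
    stroke_features,
    summarize_trial,
)
from .segmentation import complete, segment
from .simulate import CohortSpec, PianistRecord, Trial, simulate_cohort
from .trace import KeyTrace, differentiate, lowpass


def analyze_trial(traces: dict[int, KeyTrace], condition: str,
                  chords=((60, 64), (62, 65)), lowpass_hz: float | None = 20.0,
                  chord_onset_mode: str = "mean", signed_balance: bool = False,
                  **segment_kw) -> TrialSummary:
    """Run the full measurement pipeline on one trial's traces.

    Filters (optional), differentiates, segments each key, pools complete
    strokes across keys for the inter-strike statistics, pairs chords, and
    computes the condition's metric (IOI for ``fastest``, loudness balance
    for ``paced``).

    ``lowpass_hz=None`` skips filtering — appropriate for clean synthetic
    traces, where the 20 Hz default would bias peak velocities (see the
    methods note).
    """
    events, feats = {}, {}
    for key, tr in traces.items():
        if lowpass_hz is not None:
            tr = lowpass(tr, cutoff_hz=lowpass_hz)
        tr = differentiate(tr)
        evs = complete(segment(tr, **segment_kw))
        events[key] = evs
        feats[key] = {id(e): stroke_features(e, tr) for e in evs}

    pooled = [f for key in traces for f in feats[key].values()]

    pairs_by_chord = []
    for a, b in chords:
        pairs, _ = pair_chords(events.get(a, []), events.get(b, []))
        pairs_by_chord.append(((a, b), pairs))

    ioi = bal = None
    if condition == "fastest":
        onsets = np.sort(np.concatenate([
            chord_onsets(pairs, mode=chord_onset_mode)
            for _, pairs in pairs_by_chord if pairs] or [np.array([])]))
        ioi = fastest_ioi(onsets)
    elif condition == "paced":
        paired_feats = [(feats[a][id(ea)], feats[b][id(eb)])
                        for (a, b), pairs in pairs_by_chord for ea, eb in pairs]
        bal = loudness_balance(paired_feats, signed=signed_balance)
    else:
        raise ValueError(f"unknown condition {condition!r}")

    return summarize_trial(pooled, condition, ioi_ms=ioi, loudness_balance_mm_s=bal)


def build_cohort_table(records: list[PianistRecord],
                       lowpass_hz: float | None = None,
                       **analyze_kw) -> pd.DataFrame:
    """Measure every pianist's trials and assemble the cohort table.

    One row per pianist: 12 predictors from the fastest trial, plus the
    ``fastest_ioi`` (ms) and ``loudness_balance`` (mm/s) outcomes.
    """
    rows = []
    for rec in records:
        fast = analyze_trial(rec.trials["fastest"].traces, "fastest",
                             chords=rec.trials["fastest"].chords,
                             lowpass_hz=lowpass_hz, **analyze_kw)
        paced = analyze_trial(rec.trials["paced"].traces, "paced",
                              chords=rec.trials["paced"].chords,
                              lowpass_hz=lowpass_hz, **analyze_kw)
        row = {"pianist_id": rec.pianist_id}
        row.update(fast.predictor_row())
        row["fastest_ioi"] = fast.ioi_ms
        row["loudness_balance"] = paced.loudness_balance_mm_s
        rows.append(row)
    df = pd.DataFrame(rows)
    missing = df.isna().any()
    if missing.any():
        raise InsufficientDataError(
            f"cohort table has missing cells in {list(df.columns[missing])}")
    return df


@dataclass
class CohortAnalysis:
    table: pd.DataFrame                  # raw units
    ztable: pd.DataFrame                 # standardized predictors + outcomes
    fits: dict[str, regression.NetFit]
    correlation: regression.CorrelationResult


def analyze_cohort(table: pd.DataFrame, cv_folds: int = 5, seed: int = 0,
                   **fit_kw) -> CohortAnalysis:
    """Standardize the cohort table, fit both outcome models, and compute
    the outcome-outcome correlation (on the raw outcomes)."""
    ztable, _ = standardize_cohort(table)
    fits = {out: regression.fit_elastic_net(ztable, out, cv_folds=cv_folds,
                                            seed=seed, **fit_kw)
            for out in OUTCOME_COLUMNS}
    corr = regression.outcome_correlation(table["fastest_ioi"],
                                          table["loudness_balance"])
    return CohortAnalysis(table=table, ztable=ztable, fits=fits, correlation=corr)


def standardize_cohort(table: pd.DataFrame):
    cols = [c for c in table.columns if c != "pianist_id"]
    return regression.standardize(table, columns=cols)


def run_cohort_pipeline(spec: CohortSpec | None = None, noise_spec=None,
                        lowpass_hz: float | None = None, duration_s: float = 6.0,
                        cv_folds: int = 5, seed: int = 0) -> CohortAnalysis:
    """Simulate a cohort, measure it, and fit the skill regression."""
    spec = spec or CohortSpec()
    records = simulate_cohort(spec, duration_s=duration_s, noise_spec=noise_spec)
    table = build_cohort_table(records, lowpass_hz=lowpass_hz)
    return analyze_cohort(table, cv_folds=cv_folds, seed=seed)
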