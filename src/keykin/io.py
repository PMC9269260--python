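"""CSV readers/writers for traces, events and cohort tables.

All on-disk formats are plain CSV: trace tables have a ``time_ms`` column
plus one ``key_<id>`` column per key (positions in mm, downward positive);
event tables one row per stroke; cohort tables one row per pianist.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import StrokeEvent
from .trace import KeyTrace


def traces_to_frame(traces: dict[int, KeyTrace]) -> pd.DataFrame:
    first = next(iter(traces.values()))
    df = pd.DataFrame({"time_ms": first.t})
    for k in sorted(traces):
        df[f"key_{k}"] = traces[k].x
    return df


def write_traces(traces: dict[int, KeyTrace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False, float_format="%.4f")


def read_traces(path, depth_range_mm: float = 10.0) -> dict[int, KeyTrace]:
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy(dtype=float)
    out = {}
    for col in df.columns:
        if col.startswith("key_"):
            out[int(col.removeprefix("key_"))] = KeyTrace(
                int(col.removeprefix("key_")), t.copy(),
                df[col].to_numpy(dtype=float), depth_range_mm=depth_range_mm)
    return out


def events_to_frame(events: dict[int, list[StrokeEvent]]) -> pd.DataFrame:
    rows = [{"key_id": k, "onset_ms": e.onset_ms, "bottom_arrival_ms": e.bottom_arrival_ms,
             "release_ms": e.release_ms, "offset_ms": e.offset_ms,
             "truncated": e.truncated}
            for k in sorted(events) for e in events[k]]
    return pd.DataFrame(rows)


def write_events(events: dict[int, list[StrokeEvent]], path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events(path) -> dict[int, list[StrokeEvent]]:
    # round_trip parser: event times must survive CSV to the last ulp
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[int, list[StrokeEvent]] = {}
    for r in df.itertuples():
        out.setdefault(int(r.key_id), []).append(StrokeEvent(
            r.onset_ms, r.bottom_arrival_ms, r.release_ms, r.offset_ms,
            truncated=bool(r.truncated)))
    return out


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
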