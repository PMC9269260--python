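#!/usr/bin/env python
"""Simulate the 49-pianist chord-trill cohort and measure it.

Generates every pianist's fastest-tempo and paced (100 bpm) 6 s trials,
passes the analytic trajectories through the simulated acquisition chain
(12-bit quantization, 0.01 mm reporting, ground noise), then runs the
measurement pipeline: segmentation, per-stroke features, inter-strike
statistics, IOI and loudness balance.

Writes results/cohort_table.csv (one row per pianist: 12 predictors + 2
outcomes) and results/cohort_truth.csv (latent traits and programmed
parameters, for downstream sanity checks).
"""

from pathlib import Path

import pandas as pd

from keykin.pipeline import build_cohort_table
from keykin.sensor import SensorNoiseSpec
from keykin.simulate import CohortSpec, simulate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2026


def main() -> None:
    spec = CohortSpec(n_pianists=49, seed=SEED)
    records = simulate_cohort(spec, noise_spec=SensorNoiseSpec())
    table = build_cohort_table(records)

    truth = pd.DataFrame([
        {"pianist_id": r.pianist_id, **r.traits,
         "programmed_ioi_ms": 1000.0 / r.spec.rate_fastest_hz,
         "programmed_balance_mm_s": r.spec.balance_error_mm_s,
         "peak_des_vel_mm_s": r.spec.peak_des_vel,
         "dwell_fastest_ms": r.spec.dwell_fastest_ms,
         "ascent_ms": r.spec.ascent_ms}
        for r in records])

    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "cohort_table.csv", index=False, float_format="%.6f")
    truth.to_csv(RESULTS / "cohort_truth.csv", index=False, float_format="%.6f")

    merged = table.merge(truth, on="pianist_id")
    r_ioi = merged["fastest_ioi"].corr(merged["programmed_ioi_ms"])
    r_bal = merged["loudness_balance"].corr(merged["programmed_balance_mm_s"])
    print(f"cohort of {len(table)} pianists measured through the sensor chain")
    print(f"  measured IOI vs programmed IOI      r = {r_ioi:.3f}")
    print(f"  measured balance vs programmed      r = {r_bal:.3f}")
    print(f"  IOI range: {table['fastest_ioi'].min():.1f}-"
          f"{table['fastest_ioi'].max():.1f} ms; "
          f"balance range: {table['loudness_balance'].min():.1f}-"
          f"{table['loudness_balance'].max():.1f} mm/s")
    print(f"wrote {RESULTS / 'cohort_table.csv'} and {RESULTS / 'cohort_truth.csv'}")


if __name__ == "__main__":
    main()
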