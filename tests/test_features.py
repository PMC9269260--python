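"""Per-stroke features, trial statistics, IOI and loudness balance."""

import math

import numpy as np
import pytest
from scipy import stats

from keykin.errors import (
    InsufficientDataError,
    InsufficientStrokesError,
    InvariantViolationError,
)
from keykin.features import (
    FEATURE_NAMES,
    chord_onsets,
    fastest_ioi,
    loudness_balance,
    pair_chords,
    stroke_features,
    summarize_trial,
)
from keykin.segmentation import StrokeEvent, segment
from keykin.simulate import AnalyticStroke, PianistSpec, StrokeSpec, simulate_trial
from keykin.trace import KeyTrace, differentiate

from conftest import match_strokes


class TestStrokeFeatures:
    def test_min_jerk_closed_form(self, canonical_stroke, canonical_trace):
        """Symmetric min-jerk stroke: peak velocities 1.875*d/T = 375 mm/s at
        the phase midpoints, depression ratio 100/200 = 0.5."""
        f = stroke_features(canonical_stroke.events, canonical_trace)
        assert f.peak_des_vel == pytest.approx(375.0, rel=0.01)
        assert f.peak_asc_vel == pytest.approx(375.0, rel=0.01)
        assert f.max_depth == pytest.approx(10.0, abs=0.01)
        assert f.peak_to_bottom == pytest.approx(25.0, abs=1.0)
        assert f.release_to_peak == pytest.approx(25.0, abs=1.0)
        assert f.depression_ratio == pytest.approx(0.5, abs=0.005)

    def test_vanishing_dwell_limit(self):
        s = AnalyticStroke(StrokeSpec(50, 0.5, 50, 10))
        tr = differentiate(s.sample().with_(v=None))
        f = stroke_features(s.events, tr)
        assert f.depression_ratio < 0.01

    def test_time_scaling_law(self):
        """Stretching time by 2 halves both peak velocities, doubles both
        durations, and leaves depth and depression ratio unchanged."""
        base = AnalyticStroke(StrokeSpec(50, 100, 50, 10))
        slow = AnalyticStroke(StrokeSpec(100, 200, 100, 10))
        fb = stroke_features(base.events, differentiate(base.sample().with_(v=None)))
        fs = stroke_features(slow.events, differentiate(slow.sample().with_(v=None)))
        assert fs.peak_des_vel == pytest.approx(fb.peak_des_vel / 2, rel=0.01)
        assert fs.peak_asc_vel == pytest.approx(fb.peak_asc_vel / 2, rel=0.01)
        assert fs.peak_to_bottom == pytest.approx(2 * fb.peak_to_bottom, abs=1.5)
        assert fs.release_to_peak == pytest.approx(2 * fb.release_to_peak, abs=1.5)
        assert fs.max_depth == pytest.approx(fb.max_depth, abs=0.01)
        assert fs.depression_ratio == pytest.approx(fb.depression_ratio, abs=0.005)

    def test_invariant_under_position_offset(self, canonical_stroke, canonical_trace):
        shifted = differentiate(canonical_trace.with_(x=canonical_trace.x + 0.37, v=None))
        f0 = stroke_features(canonical_stroke.events, canonical_trace)
        f1 = stroke_features(canonical_stroke.events, shifted)
        for name in FEATURE_NAMES:
            assert getattr(f1, name) == pytest.approx(getattr(f0, name), abs=1e-9)

    def test_time_reversal_swaps_descent_and_ascent(self):
        """Reversing an asymmetric stroke swaps peak_des_vel <-> peak_asc_vel
        and peak_to_bottom <-> release_to_peak."""
        s = AnalyticStroke(StrokeSpec(40, 100, 60, 10, onset_ms=0.0))
        tr = differentiate(s.sample(pad_ms=50.0).with_(v=None))
        f = stroke_features(s.events, tr)
        t_end = tr.t[-1] + tr.t[0]
        rev = differentiate(tr.with_(x=tr.x[::-1].copy(), v=None))
        ev = s.events
        rev_ev = StrokeEvent(t_end - ev.offset_ms, t_end - ev.release_ms,
                             t_end - ev.bottom_arrival_ms, t_end - ev.onset_ms)
        fr = stroke_features(rev_ev, rev)
        assert fr.peak_des_vel == pytest.approx(f.peak_asc_vel, rel=0.01)
        assert fr.peak_asc_vel == pytest.approx(f.peak_des_vel, rel=0.01)
        assert fr.peak_to_bottom == pytest.approx(f.release_to_peak, abs=1.0)
        assert fr.release_to_peak == pytest.approx(f.peak_to_bottom, abs=1.0)
        assert fr.max_depth == pytest.approx(f.max_depth, abs=1e-9)
        assert fr.depression_ratio == pytest.approx(f.depression_ratio, abs=1e-9)

    def test_velocity_required(self, canonical_stroke):
        tr = canonical_stroke.sample().with_(v=None)
        with pytest.raises(InvariantViolationError):
            stroke_features(canonical_stroke.events, tr)


class TestSummarizeTrial:
    def _feat(self, vel):
        s = AnalyticStroke(StrokeSpec(1.875e4 / vel, 100, 50, 10))
        return s.true_features

    def test_identical_strokes_zero_sd(self):
        summ = summarize_trial([self._feat(300)] * 5, "fastest")
        assert all(v == 0.0 for v in summ.sds.values())
        assert summ.n_strokes == 5

    def test_two_point_sample_sd(self):
        summ = summarize_trial([self._feat(300), self._feat(400)], "fastest")
        assert summ.means["peak_des_vel"] == pytest.approx(350.0)
        assert summ.sds["peak_des_vel"] == pytest.approx(70.71, abs=0.01)

    def test_single_stroke_rejected(self):
        with pytest.raises(InsufficientStrokesError):
            summarize_trial([self._feat(300)], "fastest")

    def test_programmed_velocity_sd_within_chi_band(self):
        """The inter-strike SD of peak descending velocity, taken over one
        key's ground-truth strokes, sits inside the 95% sampling band of a
        sample SD at the realized n."""
        p = PianistSpec(vel_sd_frac=0.05, balance_error_mm_s=30.0)
        trial = simulate_trial(p, "fastest", seed=123)
        vels = np.array([f.peak_des_vel for f in trial.true_features[60]])
        n = vels.size
        # per-stroke velocity = v0(1+eps) +- dv/2 with independent draws
        sigma = math.sqrt((375.0 * 0.05) ** 2
                          + (30.0 * math.sqrt(math.pi / 2)) ** 2 / 4)
        lo, hi = stats.chi2.ppf([0.025, 0.975], df=n - 1)
        band = sigma * np.sqrt(np.array([lo, hi]) / (n - 1))
        assert band[0] <= vels.std(ddof=1) <= band[1]


class TestPairChords:
    def _ev(self, onset, cycle=200.0, dwell=100.0, descent=50.0):
        return StrokeEvent(onset, onset + descent, onset + descent + dwell,
                           onset + cycle)

    def test_synchronous_strokes_all_paired(self):
        a = [self._ev(o) for o in (0, 500, 1000)]
        b = [self._ev(o) for o in (0, 500, 1000)]
        pairs, orphans = pair_chords(a, b)
        assert len(pairs) == 3 and orphans == []

    def test_extra_stroke_orphaned(self):
        a = [self._ev(o) for o in (0, 500, 1000)]
        b = [self._ev(o) for o in (0, 1000)]
        pairs, orphans = pair_chords(a, b)
        assert len(pairs) == 2
        assert orphans == [a[1]]

    def test_offset_within_cycle_still_paired(self):
        # 30 ms asynchrony against 150 ms depression intervals
        a = [self._ev(o, cycle=150, dwell=60, descent=45) for o in (0, 300)]
        b = [self._ev(o + 30, cycle=150, dwell=60, descent=45) for o in (0, 300)]
        pairs, orphans = pair_chords(a, b)
        assert len(pairs) == 2 and orphans == []


class TestFastestIOI:
    def test_uniform_sequence(self):
        assert fastest_ioi([0, 125, 250, 375]) == pytest.approx(125.0)

    def test_mean_of_differences(self):
        assert fastest_ioi([0, 100, 160]) == pytest.approx(80.0)

    def test_too_few_strikes(self):
        with pytest.raises(InsufficientDataError):
            fastest_ioi([0, 125])

    def test_exact_for_noise_free_uniform_strikes(self):
        onsets = np.arange(12) * 137.0
        assert fastest_ioi(onsets) == pytest.approx(137.0, abs=1e-12)

    def test_simulated_rate_recovered(self):
        """8 chord strikes/s with 5 ms onset jitter: the measured mean IOI
        stays within [120, 130] ms of the programmed 125 ms."""
        trial = simulate_trial(PianistSpec(rate_fastest_hz=8.0), "fastest", seed=7)
        ioi = fastest_ioi(trial.chord_onsets_ms)
        assert 120.0 <= ioi <= 130.0


class TestLoudnessBalance:
    def _pair(self, va, vb):
        fa = AnalyticStroke(StrokeSpec(1.875e4 / va, 100, 50, 10)).true_features
        fb = AnalyticStroke(StrokeSpec(1.875e4 / vb, 100, 50, 10)).true_features
        return fa, fb

    def test_equal_velocities_zero(self):
        assert loudness_balance([self._pair(350, 350)] * 3) == 0.0

    def test_single_chord_difference(self):
        assert loudness_balance([self._pair(350, 300)]) == pytest.approx(50.0)

    def test_symmetric_in_the_two_keys(self):
        pairs = [self._pair(350, 310), self._pair(290, 330)]
        flipped = [(b, a) for a, b in pairs]
        assert loudness_balance(pairs) == pytest.approx(loudness_balance(flipped))

    def test_signed_mean_can_cancel(self):
        pairs = [self._pair(350, 300), self._pair(300, 350)]
        assert loudness_balance(pairs, signed=True) == pytest.approx(0.0, abs=1e-9)
        assert loudness_balance(pairs) == pytest.approx(50.0)

    def test_empty_pairing_rejected(self):
        with pytest.raises(InsufficientDataError):
            loudness_balance([])

    def test_programmed_balance_error_recovered(self):
        """Planted mean |dv| of 30 mm/s is recovered within 20% from the
        ground-truth features (long trial, so Monte-Carlo error is small:
        ~100 chords gives an SE of ~2.3 mm/s on the mean)."""
        trial = simulate_trial(PianistSpec(balance_error_mm_s=30.0), "paced",
                               duration_s=30.0, seed=21)
        pairs = [(fa, fb) for a, b in trial.chords
                 for fa, fb in zip(trial.true_features[a], trial.true_features[b])]
        assert loudness_balance(pairs) == pytest.approx(30.0, rel=0.2)


class TestFullPipelineRecovery:
    def test_features_recovered_from_converted_traces(self):
        """Segment + features on sensorized-then-converted traces match the
        generator's ground truth: velocities within 2%, event-derived
        durations within 3 ms (quantized, unfiltered route)."""
        from keykin.sensor import (CalibrationTable, SensorNoiseSpec,
                                   convert_counts_to_position, sensorize)
        trial = simulate_trial(PianistSpec(), "fastest", seed=31)
        cal = CalibrationTable.uniform(trial.traces.keys())
        noise = SensorNoiseSpec(linearity_error_amplitude=0.0,
                                sampling_jitter_sd_ms=0.0, clock_scale_error=0.0)
        conv = convert_counts_to_position(sensorize(trial.traces, cal, noise, seed=5), cal)
        checked = 0
        for key, tr in conv.items():
            tr = differentiate(tr)
            events = segment(tr)
            for te, me in match_strokes(trial.true_events[key], events):
                truth = trial.true_features[key][trial.true_events[key].index(te)]
                got = stroke_features(me, tr)
                assert got.peak_des_vel == pytest.approx(truth.peak_des_vel, rel=0.02)
                assert got.peak_asc_vel == pytest.approx(truth.peak_asc_vel, rel=0.02)
                assert got.peak_to_bottom == pytest.approx(truth.peak_to_bottom, abs=3.0)
                assert got.release_to_peak == pytest.approx(truth.release_to_peak, abs=3.0)
                assert got.max_depth == pytest.approx(truth.max_depth, abs=0.05)
                checked += 1
        assert checked >= 40
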