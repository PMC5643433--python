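"""Gaze resampling, closure-gap removal, I-DT parsing and windowed features."""

import numpy as np
import pandas as pd
import pytest
from idt_oracle import idt_bruteforce

from vrstim import (
    FixationEvent,
    SaccadeEvent,
    detect_fixations_idt,
    remove_closure_gaps,
    resample_to_60hz,
    sliding_window_features,
)
from conftest import random_gaze_trace


def trace(t, x, y, valid=None):
    t = np.asarray(t, dtype=float)
    return pd.DataFrame({
        "t_s": t,
        "x_deg": np.broadcast_to(np.asarray(x, dtype=float), t.shape).copy(),
        "y_deg": np.broadcast_to(np.asarray(y, dtype=float), t.shape).copy(),
        "valid": True if valid is None else valid,
    })


class TestResample:
    def test_uniform_60hz_input_is_identity(self):
        t = np.arange(120) / 60.0
        df = trace(t, np.sin(t), np.cos(t))
        out = resample_to_60hz(df)
        assert np.allclose(out["t_s"], t)
        assert np.allclose(out["x_deg"], df["x_deg"])
        assert np.allclose(out["y_deg"], df["y_deg"])

    def test_30hz_linear_ramp_interpolates_exactly(self):
        t = np.arange(30) / 30.0
        df = trace(t, t, 2 * t)  # x(t) = t lies on a line
        out = resample_to_60hz(df)
        assert np.allclose(out["x_deg"], out["t_s"])
        assert np.allclose(out["y_deg"], 2 * out["t_s"])

    def test_120hz_input_halves_sample_count(self):
        t = np.arange(240) / 120.0
        out = resample_to_60hz(trace(t, 0.0, 0.0))
        assert abs(len(out) - 120) <= 1

    def test_unsorted_timestamps_rejected(self):
        df = trace([0.0, 0.2, 0.1], 0.0, 0.0)
        with pytest.raises(ValueError, match="increasing"):
            resample_to_60hz(df)

    def test_validity_requires_both_bracketing_samples(self):
        t = np.arange(10) / 30.0  # 30 Hz -> new points between inputs
        valid = np.ones(10, dtype=bool)
        valid[4] = False
        out = resample_to_60hz(trace(t, 0.0, 0.0, valid))
        # points bracketed by (3,4) or (4,5), and the point at sample 4, invalid
        bad = (out["t_s"] > t[3]) & (out["t_s"] < t[5])
        assert not out.loc[bad, "valid"].any()
        assert out.loc[~bad, "valid"].all()


class TestClosureGaps:
    def _with_gap(self, run):
        n = 120
        valid = np.ones(n, dtype=bool)
        valid[50:50 + run] = False
        return trace(np.arange(n) / 60.0, 1.0, 1.0, valid)

    def test_run_of_21_invalid_frames_deleted(self):
        out = remove_closure_gaps(self._with_gap(21))
        assert len(out) == 120 - 21
        assert out["valid"].all()

    def test_run_of_exactly_20_frames_retained_and_interpolated(self):
        out = remove_closure_gaps(self._with_gap(20))
        assert len(out) == 120
        assert out["valid"].all()
        assert np.allclose(out["x_deg"], 1.0)

    def test_all_valid_trace_is_identity(self):
        df = self._with_gap(0)
        out = remove_closure_gaps(df)
        pd.testing.assert_frame_equal(out, df)


class TestIDT:
    def test_constant_200ms_gaze_is_one_fixation(self):
        df = trace(np.arange(13) / 60.0, 3.0, -2.0)  # spans exactly 200 ms
        fix, sacc = detect_fixations_idt(df)
        assert len(fix) == 1 and len(sacc) == 0
        assert fix[0].duration_ms == pytest.approx(200.0)
        assert fix[0].cx == pytest.approx(3.0)

    def test_two_clusters_give_saccade_of_centroid_distance(self):
        t = np.arange(20) / 60.0  # two 10-sample (150 ms) clusters
        x = np.where(np.arange(20) < 10, 0.0, 10.0)
        fix, sacc = detect_fixations_idt(trace(t, x, 0.0))
        assert len(fix) == 2 and len(sacc) == 1
        assert sacc[0].amplitude == pytest.approx(10.0)

    def test_fast_ramp_yields_no_fixations(self):
        t = np.arange(300) / 60.0
        x = 30.0 * t  # 0.5 deg per sample -> >2 deg dispersion per 100 ms
        fix, _ = detect_fixations_idt(trace(t, x, 0.0))
        assert fix == []

    @pytest.mark.parametrize("n,expected", [(7, 1), (6, 0)])
    def test_minimum_duration_is_inclusive(self, n, expected):
        # 7 samples at 60 Hz span exactly 100 ms; 6 span ~83 ms
        fix, _ = detect_fixations_idt(trace(np.arange(n) / 60.0, 0.0, 0.0))
        assert len(fix) == expected

    def test_empty_input_gives_empty_outputs(self):
        fix, sacc = detect_fixations_idt(trace([], 0.0, 0.0))
        assert fix == [] and sacc == []

    def test_agrees_with_bruteforce_oracle_on_random_traces(self, rng):
        dt = 1.0 / 60.0
        for _ in range(20):
            df = random_gaze_trace(rng, n_max=800)
            fix, _ = detect_fixations_idt(df)
            oracle = idt_bruteforce(df["t_s"].to_numpy(), df["x_deg"].to_numpy(),
                                    df["y_deg"].to_numpy(), 0.1, 2.0)
            assert len(fix) == len(oracle)
            for f, (i, j) in zip(fix, oracle):
                assert abs(f.start - df["t_s"].iloc[i]) <= dt + 1e-9
                assert abs(f.end - df["t_s"].iloc[j]) <= dt + 1e-9

    def test_fixation_time_conserved_and_disjoint(self, rng):
        df = random_gaze_trace(rng)
        fix, _ = detect_fixations_idt(df)
        total = sum(f.end - f.start for f in fix)
        span = df["t_s"].iloc[-1] - df["t_s"].iloc[0]
        assert 0.0 <= total <= span + 1e-9
        for a, b in zip(fix, fix[1:]):
            assert a.end < b.start + 1e-9

    def test_raising_dispersion_never_decreases_fixation_time(self, rng):
        df = random_gaze_trace(rng)
        totals = []
        for disp in (1.0, 2.0, 4.0, 8.0):
            fix, _ = detect_fixations_idt(df, max_dispersion_deg=disp)
            totals.append(sum(f.end - f.start for f in fix))
        assert all(b >= a - 1e-9 for a, b in zip(totals, totals[1:]))


class TestWindowFeatures:
    def _stationary_events(self, duration_s=300.0):
        # one 200 ms fixation starting each second
        fix = [FixationEvent(start=k, end=k + 0.2, cx=0.0, cy=0.0)
               for k in range(int(duration_s))]
        sacc = [SaccadeEvent(start=f.end, end=g.start, amplitude=5.0)
                for f, g in zip(fix, fix[1:])]
        return fix, sacc

    def test_stationary_rates_in_interior_windows(self):
        fix, sacc = self._stationary_events()
        times = np.arange(0, 300.0, 1.0)
        out = sliding_window_features(fix, sacc, times, np.zeros_like(times),
                                      trace_span=(0.0, 300.0))
        interior = out[(out["t_s"] > 31) & (out["t_s"] < 269)]
        assert np.allclose(interior["n_fix_per_s"], 1.0, atol=0.05)
        assert np.allclose(interior["fix_dur_ms_per_s"], 200.0, atol=10.0)
        assert np.allclose(interior["sacc_amp_deg"], 5.0)

    def test_no_saccades_gives_missing_ratio(self):
        fix = [FixationEvent(0.0, 1.0, 0.0, 0.0)]
        out = sliding_window_features(fix, [], np.array([0.5]), np.array([0]),
                                      trace_span=(0.0, 1.0))
        assert np.isnan(out["fix_sacc_ratio"].iloc[0])
        assert np.isnan(out["sacc_amp_deg"].iloc[0])
        assert out["fix_dur_ms_per_s"].iloc[0] == pytest.approx(1000.0)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError, match="window_s"):
            sliding_window_features([], [], np.array([0.0]), np.array([0]), window_s=0)

    def test_target_windows_have_higher_ratio_when_fixations_longer(self):
        # longer fixations (less saccade time) inside the target half
        fix, sacc = [], []
        for k in range(300):
            dur = 0.8 if k >= 150 else 0.2
            fix.append(FixationEvent(k, k + dur, 0.0, 0.0))
        sacc = [SaccadeEvent(f.end, g.start, 3.0) for f, g in zip(fix, fix[1:])]
        times = np.arange(0.0, 300.0)
        target = (times >= 150).astype(int)
        out = sliding_window_features(fix, sacc, times, target, trace_span=(0.0, 300.0))
        assert (out.loc[out["target"] == 1, "fix_sacc_ratio"].mean()
                > out.loc[out["target"] == 0, "fix_sacc_ratio"].mean())
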