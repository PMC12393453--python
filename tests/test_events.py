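"""Event calling: windowed minima, thresholding, dynamics, persistence, raster."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from capnet.events import (
    build_raster,
    call_events,
    classify_dynamics,
    compute_dynamics,
    detect_persistent,
    events_to_table,
    raster_to_events,
    window_minima,
)
from conftest import brute_force_events


class TestWindowMinima:
    def test_constant_trace(self):
        ref = window_minima(np.full(300, 100.0), window=100)
        assert (ref == 100.0).all()

    def test_piecewise_step(self):
        trace = np.full(200, 150.0)
        trace[30] = 80.0
        trace[130] = 120.0
        ref = window_minima(trace, window=100)
        assert (ref[:100] == 80.0).all()
        assert (ref[100:] == 120.0).all()

    def test_window_spanning_whole_trace_is_global_min(self, rng):
        trace = rng.uniform(50, 200, 257)
        ref = window_minima(trace, window=1000)
        assert (ref == trace.min()).all()

    def test_short_last_window(self):
        trace = np.concatenate([np.full(100, 50.0), np.full(30, 70.0)])
        ref = window_minima(trace, window=100)
        assert (ref[100:] == 70.0).all()


class TestCallEvents:
    def test_single_excursion_duration(self):
        trace = np.full(300, 100.0)
        trace[50:56] = 160.0
        events = call_events(trace)
        assert len(events) == 1
        ev = events[0]
        assert (ev.start_frame, ev.end_frame) == (50, 55)
        assert ev.n_frames() * 3.44 == pytest.approx(20.64)
        assert not ev.censored

    def test_exact_threshold_is_not_an_event(self):
        # the threshold is strict: 150 == 1.5 x 100 does not qualify
        trace = np.full(300, 100.0)
        trace[50:56] = 150.0
        assert call_events(trace) == []

    def test_event_crossing_window_seam_is_merged(self):
        trace = np.full(300, 100.0)
        trace[98:103] = 160.0
        events = call_events(trace, window=100)
        assert [(e.start_frame, e.end_frame) for e in events] == [(98, 102)]
        assert brute_force_events(trace) == [(98, 102)]

    def test_boundary_events_kept_and_censored(self):
        trace = np.full(50, 100.0)
        trace[:3] = 160.0
        trace[47:] = 160.0
        events = call_events(trace, window=100)
        assert [(e.start_frame, e.end_frame, e.censored) for e in events] == [
            (0, 2, True),
            (47, 49, True),
        ]

    def test_gap_tolerance_merges_across_single_dip(self):
        trace = np.full(60, 100.0)
        trace[10:13] = 160.0
        trace[14:17] = 160.0
        assert len(call_events(trace)) == 2
        merged = call_events(trace, gap_tolerance=1)
        assert [(e.start_frame, e.end_frame) for e in merged] == [(10, 16)]

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        trace = rng.uniform(10, 300, rng.integers(5, 400))
        got = [(e.start_frame, e.end_frame) for e in call_events(trace)]
        assert got == brute_force_events(trace)

    @given(st.integers(0, 2**31 - 1))
    def test_threshold_monotonicity(self, seed):
        # raising the threshold never increases total supra-threshold frames
        rng = np.random.default_rng(seed)
        trace = rng.uniform(10, 300, 200)
        frames = [
            sum(e.n_frames() for e in call_events(trace, threshold_ratio=r))
            for r in (0.3, 0.5, 0.8)
        ]
        assert frames[0] >= frames[1] >= frames[2]


class TestComputeDynamics:
    def make_table(self, events_by_cell, frame_interval=3.44):
        return events_to_table(events_by_cell, frame_interval)

    def test_single_event_frequency_floor(self):
        from capnet.events import Event

        # one event over the 300-frame, 3.44 s/frame recording (17.2 min)
        table = self.make_table({1: [Event(50, 55)]})
        dyn = compute_dynamics(table, 300, 3.44)
        assert dyn.loc[0, "frequency"] == pytest.approx(1 / 17.2)
        # the same floor in Hz rounds to 0.001 (1 event / 1032 s)
        assert round(dyn.loc[0, "frequency"] / 60.0, 3) == 0.001

    def test_multiple_event_arithmetic(self):
        from capnet.events import Event

        table = self.make_table({1: [Event(0, 1), Event(10, 13), Event(30, 35)]})
        dyn = compute_dynamics(table, 300, 3.44)
        assert dyn.loc[0, "avg_duration"] == pytest.approx(12 * 3.44 / 3)
        assert dyn.loc[0, "frequency"] == pytest.approx(3 / 17.2)

    def test_inactive_cell(self):
        table = self.make_table({})
        dyn = compute_dynamics(table, 300, 3.44, cell_ids=[7])
        row = dyn.iloc[0]
        assert row["status"] == "inactive"
        assert row["frequency"] == 0
        assert np.isnan(row["avg_duration"])


class TestDetectPersistent:
    def test_constantly_high_trace(self):
        persistent, dur = detect_persistent(np.full(300, 180.0), 3.44)
        assert persistent and dur == pytest.approx(1032.0)

    def test_exactly_170_is_not_signaling(self):
        persistent, dur = detect_persistent(np.full(300, 170.0), 3.44)
        assert not persistent and dur == 0.0

    def test_brief_bright_transient_below_floor(self):
        trace = np.full(300, 100.0)
        trace[:30] = 200.0
        persistent, dur = detect_persistent(trace, 3.44)
        assert not persistent
        assert dur == pytest.approx(103.2)

    def test_out_of_scale_input_rejected(self):
        with pytest.raises(ValueError, match="scale_max"):
            detect_persistent(np.full(10, 300.0), 3.44)


class TestClassifyDynamics:
    def make_dynamics(self, freqs, durs=None):
        n = len(freqs)
        return pd.DataFrame(
            {
                "cell_id": range(n),
                "status": ["active"] * n,
                "n_events": [1] * n,
                "frequency": freqs,
                "avg_duration": durs if durs is not None else [10.0] * n,
            }
        )

    def test_one_sd_threshold_hand_computed(self):
        dyn = self.make_dynamics([0.1, 0.2, 0.3, 0.4, 1.0])
        out, thresholds = classify_dynamics(dyn)
        assert thresholds["frequency"] == pytest.approx(0.4 + np.std([0.1, 0.2, 0.3, 0.4, 1.0], ddof=1))
        assert thresholds["frequency"] == pytest.approx(0.7536, abs=1e-4)
        assert out["high_frequency"].tolist() == [False, False, False, False, True]

    def test_identical_population_has_no_outliers(self):
        out, _ = classify_dynamics(self.make_dynamics([0.5] * 6))
        assert not out["high_frequency"].any()
        assert not out["high_avg_duration"].any()

    def test_reference_thresholds_do_not_shift(self):
        day0 = self.make_dynamics([0.1, 0.2, 0.3, 0.4, 1.0])
        shifted = self.make_dynamics([f + 1.0 for f in [0.1, 0.2, 0.3, 0.4, 1.0]])
        _, t_self = classify_dynamics(day0)
        _, t_ref = classify_dynamics(shifted, reference=day0)
        assert t_ref == t_self

    def test_refuses_tiny_reference(self):
        with pytest.raises(ValueError, match="active"):
            classify_dynamics(self.make_dynamics([0.5]))


class TestRaster:
    def test_empty_table_gives_zero_raster(self):
        table = events_to_table({}, 3.44)
        raster, bars = build_raster(table, 20, 3.44, cell_ids=[1, 2])
        assert raster.shape == (2, 20)
        assert raster.sum() == 0

    def test_row_sum_matches_event_frames(self):
        from capnet.events import Event

        table = events_to_table({5: [Event(10, 19)]}, 3.44)
        raster, bars = build_raster(table, 30, 3.44)
        assert raster.sum() == 10
        assert bars.loc[0, "n_events"] == 1

    def test_overlapping_events_rejected(self):
        table = pd.DataFrame(
            {
                "cell_id": [1, 1],
                "start_frame": [0, 3],
                "end_frame": [5, 8],
                "duration_s": [6 * 3.44, 6 * 3.44],
                "censored": [False, False],
            }
        )
        with pytest.raises(ValueError, match="overlapping"):
            build_raster(table, 20, 3.44)

    @given(st.integers(0, 2**31 - 1))
    def test_raster_round_trip_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        from capnet.events import Event

        events = {}
        for cid in range(1, 5):
            t, evs = 0, []
            while t < 45:
                start = t + int(rng.integers(1, 6))
                end = start + int(rng.integers(0, 5))
                if end >= 50:
                    break
                evs.append(Event(start, end))
                t = end + 1
            if evs:
                events[cid] = evs
        table = events_to_table(events, 3.44)
        if len(table) == 0:
            return
        raster, _ = build_raster(table, 50, 3.44)
        back = raster_to_events(raster, 3.44, cell_ids=sorted(events))
        lhs = table[["cell_id", "start_frame", "end_frame", "duration_s"]]
        assert lhs.reset_index(drop=True).equals(back.reset_index(drop=True))
        # per-cell signaling seconds equal raster row sums x frame interval
        sums = table.groupby("cell_id")["duration_s"].sum().to_numpy()
        assert np.allclose(raster.sum(axis=1) * 3.44, sums)
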