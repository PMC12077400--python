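"""Behavior classification, transition estimation, and takeoff statistics."""

import numpy as np
import pandas as pd
import pytest

import shadowtrack as st
from shadowtrack.behavior_stats import (
    BehaviorParams,
    BehaviorSeries,
    StatsParams,
    TakeoffStat,
    aggregate_normalized,
    classify_search,
    classify_table,
    frame_speed,
    normalized_takeoffs,
    participation,
    spontaneous_rate,
    takeoff_response,
    timeseries,
    transitions,
)
from shadowtrack.iocore import EVENT_COLUMNS, TRACK_COLUMNS
from shadowtrack.simulate import truth_to_series, truth_to_tracks

BP = BehaviorParams()


def _walk(speeds_px_s, fps=30.0):
    """Path with per-frame speeds (straight line, px/s)."""
    steps = np.asarray(speeds_px_s, dtype=float) / fps
    x = np.concatenate([[0.0], np.cumsum(steps)])
    return np.column_stack([x, np.zeros_like(x)])


class TestFrameSpeed:
    def test_static_track_is_zero(self):
        xy = np.tile([3.0, 4.0], (20, 1))
        assert np.all(frame_speed(xy, 30.0) == 0.0)

    def test_unit_steps_give_30_px_s(self):
        xy = np.column_stack([np.arange(40.0), np.zeros(40)])
        np.testing.assert_allclose(frame_speed(xy, 30.0), 30.0)

    def test_l_shaped_path_is_direction_free(self):
        xy = np.array([[0, 0], [1, 0], [2, 0], [2, 1], [2, 2]], dtype=float)
        np.testing.assert_allclose(frame_speed(xy, 30.0), 30.0)

    def test_single_frame_error(self):
        with pytest.raises(ValueError):
            frame_speed(np.array([[0.0, 0.0]]), 30.0)


class TestClassifySearch:
    def test_constant_walker_inside_band_is_searching(self):
        bs = classify_search(_walk([30.0] * 120), BP)
        assert np.all(bs.labels == 2)

    def test_fast_mover_above_band_is_stationary(self):
        bs = classify_search(_walk([60.0] * 120), BP)
        assert np.all(bs.labels == 1)

    def test_zero_speed_is_stationary(self):
        bs = classify_search(np.tile([5.0, 5.0], (120, 1)), BP)
        assert np.all(bs.labels == 1)

    @pytest.mark.parametrize("speed,expect", [(6.0, 2), (52.0, 2), (5.9, 1), (52.1, 1)])
    def test_band_endpoints_inclusive(self, speed, expect):
        # fps 4 makes the boundary steps (1.5 and 13.0 px) exactly
        # representable, so the inclusive endpoints are not blurred by
        # floating-point accumulation
        params = BehaviorParams(fps=4.0)
        bs = classify_search(_walk([speed] * 120, fps=4.0), params)
        assert np.all(bs.labels == expect)

    def test_short_gap_merged_into_one_bout(self):
        """Search 60, pause 20, search 60 -> one contiguous 140-frame bout."""
        speeds = [30.0] * 60 + [0.0] * 20 + [30.0] * 59
        bs = classify_search(_walk(speeds), BP)
        assert len(bs.labels) == 140
        assert np.all(bs.labels == 2)

    def test_long_gap_not_merged(self):
        speeds = [30.0] * 90 + [0.0] * 89 + [30.0] * 90
        bs = classify_search(_walk(speeds), BP)
        assert np.any(bs.labels == 1)
        # the stationary stretch survives in the middle
        mid = slice(110, 160)
        assert np.all(bs.labels[mid] == 1)


class TestTransitions:
    def test_all_stationary_never_switches(self):
        series = [BehaviorSeries(0, 0, np.ones(300, np.int8), False)]
        est = transitions(series, StatsParams(n_transition_samples=2000, seed=0))
        assert est["stationary", "stationary"] == 1.0
        assert est["stationary", "searching"] == 0.0
        assert est["stationary", "takeoff"] == 0.0
        assert est.matrix.loc["stationary"].sum() == pytest.approx(1.0)
        # no searching bin was ever observed: that row is undefined, not zero
        assert est.n_valid["searching"] == 0
        assert est.matrix.loc["searching"].isna().all()

    def test_exhaustive_matches_hand_computed_oracle(self):
        """120 stationary then 120 searching frames: 181 bins, scored by hand.

        Stationary starts s=0..119; the bin holds >30 searching frames iff
        s >= 91, so 29/120 switch and 91/120 stay.  Searching starts
        (s=120..180) all stay.
        """
        labels = np.concatenate([np.ones(120, np.int8), np.full(120, 2, np.int8)])
        series = [BehaviorSeries(0, 0, labels, False)]
        est = transitions(series, StatsParams(), exhaustive=True)
        assert est.n_valid["stationary"] == 120
        assert est.n_valid["searching"] == 61
        assert est["stationary", "searching"] == pytest.approx(29 / 120)
        assert est["stationary", "stationary"] == pytest.approx(91 / 120)
        assert est["searching", "searching"] == 1.0

    def test_takeoff_scoring_of_truncated_bins(self):
        """100 stationary frames ending in takeoff: bins reaching the last
        frame (s >= 40) score takeoff, earlier bins stay."""
        series = [BehaviorSeries(0, 0, np.ones(100, np.int8), True, 99)]
        est = transitions(series, StatsParams(), exhaustive=True)
        assert est.n_valid["stationary"] == 100
        assert est["stationary", "takeoff"] == pytest.approx(0.6)
        assert est["stationary", "stationary"] == pytest.approx(0.4)

    def test_sampled_estimate_close_to_exhaustive(self, small_truth):
        series = truth_to_series(small_truth)
        exact = transitions(series, StatsParams(), exhaustive=True)
        sampled = transitions(series, StatsParams(n_transition_samples=50_000, seed=9))
        dev = np.abs(sampled.matrix.to_numpy() - exact.matrix.to_numpy()).max()
        assert dev < 0.01

    def test_rows_sum_to_one_and_bounded(self, small_truth):
        series = truth_to_series(small_truth)
        est = transitions(series, StatsParams(n_transition_samples=10_000, seed=2))
        m = est.matrix.to_numpy()
        assert np.all(m >= 0) and np.all(m <= 1)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-9)

    def test_deterministic_under_seed(self, small_truth):
        series = truth_to_series(small_truth)
        p = StatsParams(n_transition_samples=5000, seed=21)
        a = transitions(series, p).matrix
        b = transitions(series, p).matrix
        pd.testing.assert_frame_equal(a, b)

    def test_no_valid_windows_error(self):
        series = [BehaviorSeries(0, 0, np.ones(10, np.int8), False)]
        with pytest.raises(ValueError, match="bin"):
            transitions(series, StatsParams())


def _fixture_tables(n_tracks=10, n_takeoff=0, takeoff_frame=40,
                    span=(0, 100), fps=30.0):
    rows, events = [], []
    for tid in range(n_tracks):
        does_take_off = tid < n_takeoff
        last = takeoff_frame if does_take_off else span[1] - 1
        for f in range(span[0], last + 1):
            rows.append((tid, f, f / fps, 10.0 * tid, 20.0, True))
        events.append(("landing", tid, span[0], span[0] / fps, 10.0 * tid, 20.0))
        kind = "takeoff" if does_take_off else "track_lost_at_video_end"
        events.append((kind, tid, last, last / fps, 10.0 * tid, 20.0))
    table = pd.DataFrame(rows, columns=TRACK_COLUMNS[:6])
    log = pd.DataFrame(events, columns=EVENT_COLUMNS)
    return table, log


class TestTakeoffResponse:
    def test_no_takeoffs_gives_zero_rate(self):
        table, log = _fixture_tables(10)
        stat = takeoff_response(table, log, (30, 67), StatsParams())
        assert stat.n_landed_pre == 10
        assert stat.obs_rate == 0.0
        assert not stat.excluded

    def test_half_take_off(self):
        table, log = _fixture_tables(10, n_takeoff=5, takeoff_frame=40)
        stat = takeoff_response(table, log, (30, 67), StatsParams())
        assert stat.obs_rate == pytest.approx(0.5)

    def test_under_ten_landed_excluded(self):
        table, log = _fixture_tables(9)
        stat = takeoff_response(table, log, (30, 67), StatsParams())
        assert stat.excluded
        assert stat.normalized is None

    def test_takeoff_outside_window_not_counted(self):
        table, log = _fixture_tables(10, n_takeoff=3, takeoff_frame=80)
        stat = takeoff_response(table, log, (30, 67), StatsParams())
        assert stat.obs_rate == 0.0

    def test_window_outside_video_error(self):
        table, log = _fixture_tables(10)
        with pytest.raises(ValueError):
            takeoff_response(table, log, (30, 200), StatsParams(), 30.0,
                             duration_frames=100)


class TestSpontaneousRate:
    def test_no_takeoffs_anywhere_gives_zero(self):
        table, log = _fixture_tables(10, span=(0, 200))
        sched = st.build_protocol("none", recording_duration=200 / 30)
        mean, summary = spontaneous_rate(table, log, sched,
                                         StatsParams(n_spont_samples=500, seed=0),
                                         30.0, 200)
        assert mean == 0.0
        assert summary["n"] > 0

    def test_deterministic_and_stable_under_more_samples(self, small_truth):
        table, log = truth_to_tracks(small_truth)
        sched = st.build_protocol("none", recording_duration=20.0)
        m1, s1 = spontaneous_rate(table, log, sched,
                                  StatsParams(n_spont_samples=4000, seed=3),
                                  30.0, small_truth.n_frames)
        m1b, _ = spontaneous_rate(table, log, sched,
                                  StatsParams(n_spont_samples=4000, seed=3),
                                  30.0, small_truth.n_frames)
        assert m1 == m1b
        m2, s2 = spontaneous_rate(table, log, sched,
                                  StatsParams(n_spont_samples=8000, seed=4),
                                  30.0, small_truth.n_frames)
        se = s1["sd"] / np.sqrt(s1["n"]) + s2["sd"] / np.sqrt(s2["n"])
        assert abs(m1 - m2) < max(2 * se, 0.02)

    def test_windows_avoid_stimulus_response_windows(self):
        # takeoffs only inside the stimulus response window: the baseline,
        # sampled away from it, must be exactly zero
        table, log = _fixture_tables(10, n_takeoff=5, takeoff_frame=910,
                                     span=(0, 4500))
        sched = st.build_protocol("standard_150s")
        mean, _ = spontaneous_rate(table, log, sched,
                                   StatsParams(n_spont_samples=2000, seed=1),
                                   30.0, 4500)
        assert mean == 0.0

    def test_no_stimulus_free_time_error(self):
        table, log = _fixture_tables(10, span=(0, 100))
        sched = st.build_protocol("flash", recording_duration=150.0)
        params = StatsParams(n_spont_samples=10, seed=0, spont_window_s=40.0)
        with pytest.raises(ValueError):
            spontaneous_rate(table, log, sched, params, 1.0, 100)


class TestNormalizedTakeoffs:
    def test_equal_rates_give_exact_zero(self):
        assert normalized_takeoffs(0.15, 0.15) == 0.0

    def test_published_flash_off_example(self):
        assert normalized_takeoffs(0.463, 0.15) == pytest.approx(0.313)

    def test_negative_when_below_baseline(self):
        assert normalized_takeoffs(0.0, 0.15) == pytest.approx(-0.15)

    def test_antisymmetric(self):
        assert normalized_takeoffs(0.7, 0.2) == -normalized_takeoffs(0.2, 0.7)

    @pytest.mark.parametrize("obs,spont", [(-0.1, 0.5), (1.1, 0.5), (0.5, 1.2)])
    def test_out_of_range_rejected(self, obs, spont):
        with pytest.raises(ValueError):
            normalized_takeoffs(obs, spont)


class TestParticipationAndTimeseries:
    def test_empty_table(self):
        table = pd.DataFrame(columns=TRACK_COLUMNS[:6]).astype(
            {"frame_idx": int, "track_id": int}
        )
        assert participation(table, 100) == 0.0

    def test_half_visible_track(self):
        table, _ = _fixture_tables(1, span=(0, 50))
        assert participation(table, 100) == pytest.approx(0.5)

    def test_thirty_always_visible(self):
        table, _ = _fixture_tables(30, span=(0, 100))
        assert participation(table, 100) == pytest.approx(30.0)

    def test_timeseries_all_landed_searching(self):
        table, log = _fixture_tables(30, span=(0, 100))
        table["behavior_label"] = "searching"
        ts = timeseries(table, 100, 30)
        assert np.all(ts.percent_landed == 100.0)
        assert np.all(ts.percent_searching_of_landed == 100.0)
        np.testing.assert_allclose(ts.mean_x_of_landed, np.mean(10.0 * np.arange(30)))

    def test_timeseries_nobody_landed(self):
        table, _ = _fixture_tables(1, span=(0, 10))
        ts = timeseries(table, 100, 30)
        assert ts.percent_landed.iloc[50] == 0.0
        assert np.isnan(ts.mean_x_of_landed.iloc[50])
        assert np.isnan(ts.percent_searching_of_landed.iloc[50])


class TestAggregation:
    def test_excluded_replicates_contribute_nothing(self):
        included = TakeoffStat(15, 9, 0.6, spont_mean=0.1, normalized=0.5,
                               excluded=False)
        excluded = TakeoffStat(5, 5, 1.0, spont_mean=0.1, normalized=None,
                               excluded=True)
        mean, sem, n = aggregate_normalized([included, excluded])
        assert (mean, n) == (0.5, 1)

    def test_mean_and_sem(self):
        stats = [TakeoffStat(15, 0, 0.0, normalized=v) for v in (0.4, 0.6)]
        mean, sem, n = aggregate_normalized(stats)
        assert mean == pytest.approx(0.5)
        assert sem == pytest.approx(np.std([0.4, 0.6], ddof=1) / np.sqrt(2))
        assert n == 2


class TestClassifyTable:
    def test_labels_written_back_and_speed_filled(self, small_truth):
        table, log = truth_to_tracks(small_truth)
        labeled, series = classify_table(table, log, BP)
        assert labeled.speed_px_per_s.notna().all()
        assert set(labeled.behavior_label.unique()) <= {"stationary", "searching"}
        assert len(series) == table.track_id.nunique()
        # terminal takeoff flags copied from the event log
        flagged = {s.track_id for s in series if s.terminal_takeoff}
        assert flagged == set(log.loc[log.event_type == "takeoff", "track_id"])
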