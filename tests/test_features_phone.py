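import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from moodstab.features import app_features, call_features, screen_features
from moodstab.features._bins import THREE_HOUR_EDGES, seconds_in_daily_window
from moodstab.ingest import clean_screen_events

from conftest import T, app_stream, call_stream, screen_stream

PERIOD = (T("2024-03-04"), T("2024-03-18"))


class TestCallFeatures:
    def test_empty_period(self):
        out = call_features(call_stream([]), PERIOD)
        for d in ("incoming", "outgoing", "rejected", "all"):
            assert out[f"call.{d}.count"] == 0
            assert math.isnan(out[f"call.{d}.peer_entropy"])
            assert math.isnan(out[f"call.{d}.mean_duration_s"])

    def test_single_peer_entropy_zero(self):
        rows = [("2024-03-05 10:00", "outgoing", 60, "amy"),
                ("2024-03-06 11:00", "outgoing", 30, "amy"),
                ("2024-03-07 12:00", "outgoing", 90, "amy")]
        out = call_features(call_stream(rows), PERIOD)
        assert out["call.outgoing.distinct_peers"] == 1
        assert out["call.outgoing.peer_entropy"] == 0.0
        assert out["call.outgoing.count"] == 3

    def test_mean_duration(self):
        rows = [("2024-03-05 10:00", "incoming", 60, "a"),
                ("2024-03-06 10:00", "incoming", 120, "b")]
        out = call_features(call_stream(rows), PERIOD)
        assert out["call.incoming.mean_duration_s"] == pytest.approx(90.0)
        assert out["call.incoming.total_duration_s"] == pytest.approx(180.0)
        assert out["call.incoming.distinct_peers"] == 2
        assert out["call.incoming.peer_entropy"] == pytest.approx(1.0)

    def test_rejected_duration_is_nan(self):
        rows = [("2024-03-05 10:00", "rejected", 0, "a")]
        out = call_features(call_stream(rows), PERIOD)
        assert out["call.rejected.count"] == 1
        assert math.isnan(out["call.rejected.total_duration_s"])
        assert math.isnan(out["call.rejected.mean_duration_s"])

    def test_hour_circular_mean(self):
        rows = [("2024-03-05 23:00", "incoming", 60, "a"),
                ("2024-03-06 01:00", "incoming", 60, "a")]
        out = call_features(call_stream(rows), PERIOD)
        assert out["call.incoming.hour_circmean"] == pytest.approx(0.0, abs=1e-9)

    def test_out_of_period_calls_excluded(self):
        rows = [("2024-03-01 10:00", "incoming", 60, "a"),
                ("2024-03-05 10:00", "incoming", 60, "b")]
        out = call_features(call_stream(rows), PERIOD)
        assert out["call.incoming.count"] == 1
        assert out["call.all.count"] == 1


def _screen(rows):
    return clean_screen_events(screen_stream(rows))


class TestScreenFeatures:
    def test_single_morning_session(self):
        rows = [("2024-03-05 10:00", "on"), ("2024-03-05 10:30", "off")]
        out = screen_features(_screen(rows), PERIOD)
        assert out["screen.morning_ratio"] == pytest.approx(1.0)
        assert out["screen.afternoon_ratio"] == pytest.approx(0.0)
        assert out["screen.night_ratio"] == pytest.approx(0.0)
        assert out["screen.daily_count_mean"] == pytest.approx(1.0)
        assert out["screen.daily_duration_mean"] == pytest.approx(1800.0)

    def test_session_duration_stats(self):
        rows = []
        for day, minutes in (("05", 10), ("06", 20), ("07", 30)):
            rows += [(f"2024-03-{day} 10:00", "on"),
                     (f"2024-03-{day} 10:{minutes}", "off")]
        out = screen_features(_screen(rows), PERIOD)
        assert out["screen.session_duration_mean"] == pytest.approx(1200.0)

    def test_boundary_split(self):
        rows = [("2024-03-05 11:30", "on"), ("2024-03-05 12:30", "off")]
        out = screen_features(_screen(rows), PERIOD)
        assert out["screen.morning_ratio"] == pytest.approx(0.5)
        assert out["screen.afternoon_ratio"] == pytest.approx(0.5)

    def test_empty(self):
        out = screen_features(_screen([]), PERIOD)
        assert out["screen.session_count"] == 0
        assert math.isnan(out["screen.morning_ratio"])

    def test_ratio_plus_early_morning_share_is_one(self):
        rows = [("2024-03-05 02:00", "on"), ("2024-03-05 02:40", "off"),
                ("2024-03-05 09:00", "on"), ("2024-03-05 09:20", "off"),
                ("2024-03-05 22:00", "on"), ("2024-03-05 23:00", "off")]
        out = screen_features(_screen(rows), PERIOD)
        total = 40 * 60 + 20 * 60 + 60 * 60
        early = 40 * 60 / total
        s = (out["screen.morning_ratio"] + out["screen.afternoon_ratio"]
             + out["screen.night_ratio"])
        assert s + early == pytest.approx(1.0)


def _app(rows):
    return app_stream(rows)


class TestAppFeatures:
    def test_only_im_sessions(self):
        rows = [("2024-03-05 10:00", "2024-03-05 10:10", "a", "instant_messaging"),
                ("2024-03-06 11:00", "2024-03-06 11:30", "a", "instant_messaging")]
        out = app_features(_app(rows), PERIOD)
        assert out["app.im_ratio"] == pytest.approx(1.0)
        assert out["app.category_entropy_count"] == 0.0
        assert out["app.instant_messaging.session_count"] == 2

    def test_uniform_four_categories_duration_entropy(self):
        cats = ["instant_messaging", "shopping", "music", "entertainment"]
        rows = [(f"2024-03-0{5 + i} 10:00", f"2024-03-0{5 + i} 10:30", "x", c)
                for i, c in enumerate(cats)]
        out = app_features(_app(rows), PERIOD)
        assert out["app.category_entropy_duration"] == pytest.approx(2.0)
        assert out["app.category_entropy_count"] == pytest.approx(2.0)
        assert out["app.im_ratio"] == pytest.approx(0.25)

    def test_boundary_split_into_two_bins(self):
        rows = [("2024-03-05 02:50", "2024-03-05 03:10", "x", "others")]
        out = app_features(_app(rows), PERIOD)
        assert out["app.others.dur_bin0"] == pytest.approx(600.0)
        assert out["app.others.dur_bin1"] == pytest.approx(600.0)
        assert out["app.others.count_bin0"] == 1.0  # counts follow the start bin
        assert out["app.others.count_bin1"] == 0.0

    def test_all_apps_aggregates(self):
        rows = [("2024-03-05 10:00", "2024-03-05 10:10", "a", "instant_messaging"),
                ("2024-03-05 14:00", "2024-03-05 14:20", "b", "shopping")]
        out = app_features(_app(rows), PERIOD)
        assert out["app.all_apps.session_count"] == 2
        assert out["app.all_apps.session_duration_mean"] == pytest.approx(900.0)

    def test_absent_category_is_nan(self):
        rows = [("2024-03-05 10:00", "2024-03-05 10:10", "a", "instant_messaging")]
        out = app_features(_app(rows), PERIOD)
        assert math.isnan(out["app.music.session_duration_mean"])
        assert out["app.music.session_count"] == 0

    def test_empty_stream(self):
        out = app_features(_app([]), PERIOD)
        assert math.isnan(out["app.category_entropy_count"])
        assert math.isnan(out["app.im_ratio"])


@settings(max_examples=50, deadline=None)
@given(st.lists(
    st.tuples(st.floats(min_value=0, max_value=13.5 * 24),
              st.floats(min_value=1 / 60, max_value=30.0)),
    min_size=1, max_size=25))
def test_bin_duration_conservation(sessions):
    """Sum over the eight 3-h bins equals total duration, whatever the
    session layout (boundary and midnight splitting conserve time)."""
    base = T("2024-03-04")
    starts = [base + pd.Timedelta(hours=h) for h, _ in sessions]
    ends = [s + pd.Timedelta(hours=d) for s, (_, d) in zip(starts, sessions)]
    total = sum((e - s).total_seconds() for s, e in zip(starts, ends))
    binned = sum(seconds_in_daily_window(starts, ends, lo, hi)
                 for lo, hi in THREE_HOUR_EDGES)
    assert binned == pytest.approx(total, rel=1e-9, abs=1e-6)
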