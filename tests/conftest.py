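import numpy as np
import pandas as pd
import pytest

from moodstab.ingest import EventStream

TZ = "Asia/Shanghai"


def T(s: str) -> pd.Timestamp:
    """Local-timezone timestamp shorthand."""
    return pd.Timestamp(s, tz=TZ)


def call_stream(rows, pid="p0") -> EventStream:
    """rows: (ts str, direction, duration_s, peer)"""
    df = pd.DataFrame(rows, columns=["ts", "direction", "duration_s", "peer"])
    df["ts"] = df["ts"].map(T)
    return EventStream(pid, "call", df.sort_values("ts").reset_index(drop=True))


def screen_stream(rows, pid="p0") -> EventStream:
    """rows: (ts str, 'on'|'off')"""
    df = pd.DataFrame(rows, columns=["ts", "event"])
    df["ts"] = df["ts"].map(T)
    return EventStream(pid, "screen", df.reset_index(drop=True))


def app_stream(rows, pid="p0") -> EventStream:
    """rows: (ts_start str, ts_end str, app_id, category)"""
    df = pd.DataFrame(rows, columns=["ts_start", "ts_end", "app_id", "category"])
    df["ts_start"] = df["ts_start"].map(T)
    df["ts_end"] = df["ts_end"].map(T)
    return EventStream(pid, "app", df.sort_values("ts_start").reset_index(drop=True))


def wristband_stream(minutes, pid="p0") -> EventStream:
    """minutes: (ts str|Timestamp, type, steps, heart_rate) — intensity fixed."""
    rows = []
    for ts, typ, steps, hr in minutes:
        rows.append({
            "ts": T(ts) if isinstance(ts, str) else ts,
            "type": typ,
            "intensity": 0.0,
            "steps": int(steps),
            "heart_rate": float("nan") if hr is None else float(hr),
        })
    if not rows:
        return EventStream(pid, "wristband", pd.DataFrame())
    df = pd.DataFrame(rows).sort_values("ts").reset_index(drop=True)
    return EventStream(pid, "wristband", df)


def sleep_night_minutes(start: str, n_min: int, deep_every: int = 0,
                        n_deep: int = 0, hr_fn=None):
    """Build (ts, type, steps, hr) tuples for a contiguous sleep run.

    Deep minutes: either every ``deep_every``-th minute, or the first
    ``n_deep`` minutes.
    """
    t0 = T(start)
    out = []
    for i in range(n_min):
        ts = t0 + pd.Timedelta(minutes=i)
        if deep_every:
            typ = "deep_sleep" if i % deep_every == 0 else "light_sleep"
        else:
            typ = "deep_sleep" if i < n_deep else "light_sleep"
        hr = None
        if hr_fn is not None:
            hour = ts.hour + ts.minute / 60.0
            hr = hr_fn(hour)
        out.append((ts, typ, 0, hr))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
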