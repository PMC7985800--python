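"""Per-period features from call logs, screen on/off events and app
usage sessions.

Conventions shared by all feature functions:

* features are returned as ``{name: float}`` with names following
  ``<stream>.<base>[.<subgroup>]``;
* a feature whose basis is absent (e.g. entropy of zero calls) is NaN,
  never a fabricated zero;
* days without any data of a stream are excluded from per-day averages;
* sessions spanning clock-bin boundaries are split proportionally.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from ..ingest import APP_CATEGORIES, CALL_DIRECTIONS, EventStream, REAL_APP_CATEGORIES, screen_sessions
from ..stats import circular_mean, circular_sd, entropy
from ._bins import THREE_HOUR_EDGES, clip_intervals, seconds_in_daily_window

Period = Tuple[pd.Timestamp, pd.Timestamp]

__all__ = ["call_features", "screen_features", "app_features"]


def _clock_hours(ts: pd.Series) -> np.ndarray:
    return (
        ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    ).to_numpy(dtype=float)


def _nan_features(names) -> Dict[str, float]:
    return {n: float("nan") for n in names}


def call_features(calls: EventStream, period: Period) -> Dict[str, float]:
    """Call-log features per direction (incoming/outgoing/rejected/all).

    Per direction: count, total and mean duration (NaN for rejected,
    whose durations are not meaningful), number of distinct peers, peer
    entropy weighted by call counts, and circular mean/SD of call clock
    hour.
    """
    df = calls.records
    if not df.empty:
        mask = (df["ts"] >= period[0]) & (df["ts"] < period[1])
        df = df.loc[mask]
    out: Dict[str, float] = {}
    for direction in CALL_DIRECTIONS + ("all",):
        sub = df if direction == "all" else (
            df.loc[df["direction"] == direction] if not df.empty else df
        )
        prefix = f"call.{direction}"
        n = len(sub)
        out[f"{prefix}.count"] = float(n)
        names = [
            f"{prefix}.total_duration_s",
            f"{prefix}.mean_duration_s",
            f"{prefix}.distinct_peers",
            f"{prefix}.peer_entropy",
            f"{prefix}.hour_circmean",
            f"{prefix}.hour_circsd",
        ]
        if n == 0:
            out.update(_nan_features(names))
            continue
        if direction == "rejected":
            out[f"{prefix}.total_duration_s"] = float("nan")
            out[f"{prefix}.mean_duration_s"] = float("nan")
        else:
            total = float(sub["duration_s"].sum())
            out[f"{prefix}.total_duration_s"] = total
            out[f"{prefix}.mean_duration_s"] = total / n
        peer_counts = sub["peer"].value_counts()
        out[f"{prefix}.distinct_peers"] = float(len(peer_counts))
        out[f"{prefix}.peer_entropy"] = entropy(peer_counts.to_dict())
        hours = _clock_hours(sub["ts"])
        out[f"{prefix}.hour_circmean"] = circular_mean(hours)
        out[f"{prefix}.hour_circsd"] = circular_sd(hours)
    return out


def screen_features(screen: EventStream, period: Period) -> Dict[str, float]:
    """Screen-usage features from cleaned alternating on/off events.

    Sessions are on->off spans clipped to the period.  Daily usage count
    and duration are averaged/medianed over days with at least one
    session; morning (6-12), afternoon (12-18) and night (18-24) ratios
    are duration shares over the whole period.
    """
    sessions = clip_intervals(screen_sessions(screen), period)
    names = [
        "screen.daily_count_mean",
        "screen.daily_count_median",
        "screen.daily_duration_mean",
        "screen.daily_duration_median",
        "screen.session_duration_mean",
        "screen.morning_ratio",
        "screen.afternoon_ratio",
        "screen.night_ratio",
    ]
    out: Dict[str, float] = {"screen.session_count": float(len(sessions))}
    if sessions.empty:
        out.update(_nan_features(names))
        return out
    dur = (sessions["ts_end"] - sessions["ts_start"]).dt.total_seconds()
    day = sessions["ts_start"].dt.normalize()
    daily_count = sessions.groupby(day).size()
    daily_dur = dur.groupby(day).sum()
    out["screen.daily_count_mean"] = float(daily_count.mean())
    out["screen.daily_count_median"] = float(daily_count.median())
    out["screen.daily_duration_mean"] = float(daily_dur.mean())
    out["screen.daily_duration_median"] = float(daily_dur.median())
    out["screen.session_duration_mean"] = float(dur.mean())
    total = float(dur.sum())
    starts = list(sessions["ts_start"])
    ends = list(sessions["ts_end"])
    for name, (lo, hi) in (
        ("screen.morning_ratio", (6, 12)),
        ("screen.afternoon_ratio", (12, 18)),
        ("screen.night_ratio", (18, 24)),
    ):
        out[name] = (
            seconds_in_daily_window(starts, ends, lo, hi) / total
            if total > 0 else float("nan")
        )
    return out


def _category_names(cat: str) -> list[str]:
    prefix = f"app.{cat}"
    names = [
        f"{prefix}.session_duration_mean",
        f"{prefix}.session_duration_sd",
        f"{prefix}.daily_count_mean",
        f"{prefix}.daily_count_sd",
    ]
    names += [f"{prefix}.dur_bin{k}" for k in range(8)]
    names += [f"{prefix}.count_bin{k}" for k in range(8)]
    return names


def app_features(apps: EventStream, period: Period) -> Dict[str, float]:
    """App-usage features per category plus cross-category entropies.

    For each of the eight categories (seven real ones plus the
    ``all_apps`` aggregate): mean/SD of session durations, mean/SD of
    daily session counts, and duration / session-count totals in each
    of the eight 3-hour clock bins.  Cross-category Shannon entropy is
    computed once over session counts and once over total durations,
    plus the instant-messaging / all-apps duration ratio.
    """
    df = clip_intervals(apps.records, period)
    out: Dict[str, float] = {}
    cat_counts: Dict[str, float] = {}
    cat_durs: Dict[str, float] = {}
    for cat in APP_CATEGORIES:
        prefix = f"app.{cat}"
        sub = df if cat == "all_apps" else (
            df.loc[df["category"] == cat] if not df.empty else df
        )
        n = len(sub)
        out[f"{prefix}.session_count"] = float(n)
        if n == 0:
            out.update(_nan_features(_category_names(cat)))
            if cat != "all_apps":
                cat_counts[cat] = 0.0
                cat_durs[cat] = 0.0
            continue
        dur = (sub["ts_end"] - sub["ts_start"]).dt.total_seconds()
        if cat != "all_apps":
            cat_counts[cat] = float(n)
            cat_durs[cat] = float(dur.sum())
        out[f"{prefix}.session_duration_mean"] = float(dur.mean())
        out[f"{prefix}.session_duration_sd"] = float(dur.std(ddof=1))
        day = sub["ts_start"].dt.normalize()
        daily = sub.groupby(day).size()
        out[f"{prefix}.daily_count_mean"] = float(daily.mean())
        out[f"{prefix}.daily_count_sd"] = float(daily.std(ddof=1))
        starts = list(sub["ts_start"])
        ends = list(sub["ts_end"])
        start_hours = _clock_hours(sub["ts_start"])
        for k, (lo, hi) in enumerate(THREE_HOUR_EDGES):
            out[f"{prefix}.dur_bin{k}"] = seconds_in_daily_window(starts, ends, lo, hi)
            out[f"{prefix}.count_bin{k}"] = float(
                ((start_hours >= lo) & (start_hours < hi)).sum()
            )
    total_count = sum(cat_counts.values())
    total_dur = sum(cat_durs.values())
    out["app.category_entropy_count"] = (
        entropy(cat_counts) if total_count > 0 else float("nan")
    )
    out["app.category_entropy_duration"] = (
        entropy(cat_durs) if total_dur > 0 else float("nan")
    )
    out["app.im_ratio"] = (
        cat_durs.get("instant_messaging", 0.0) / total_dur
        if total_dur > 0 else float("nan")
    )
    return out
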