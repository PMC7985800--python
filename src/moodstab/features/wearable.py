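"""Per-period wristband features: sleep architecture, step counts and
nightly heart-rate cosinor parameters.

The wristband emits one packet per minute typed activity / light_sleep /
deep_sleep / not_worn; heart rate is present only on sleep-typed
minutes.  Nights are maximal runs of sleep minutes with short gaps
bridged; each night is assigned to the calendar date of its onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..ingest import EventStream, SLEEP_TYPES, WORN_TYPES
from ..stats import circular_mean, circular_median, circular_sd

Period = Tuple[pd.Timestamp, pd.Timestamp]

__all__ = [
    "SleepNight",
    "CosinorFit",
    "segment_nights",
    "sleep_features",
    "step_features",
    "fit_cosinor",
    "nightly_cosinor_fits",
    "heart_rate_features",
]


@dataclass
class SleepNight:
    """One contiguous (gap-bridged) sleep episode."""

    date: pd.Timestamp          # calendar date of onset
    onset: pd.Timestamp
    wake: pd.Timestamp
    light_min: int
    deep_min: int
    valid: bool
    #: (clock hour, heart rate) pairs of the episode's sleep minutes
    hr_points: pd.DataFrame

    @property
    def total_min(self) -> int:
        return self.light_min + self.deep_min


@dataclass
class CosinorFit:
    """Single-component cosinor fit y(t) = mesor + amplitude*cos(2*pi*(t-acrophase)/period)."""

    mesor: float
    amplitude: float
    acrophase: float            # hours in [0, period)
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.r2 <= 1.0 + 1e-9:
            raise ValueError("r2 must lie in [0, 1]")


def _clock_hours(ts: pd.Series) -> np.ndarray:
    return (ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0).to_numpy(float)


def segment_nights(
    wristband: EventStream,
    period: Period,
    bridge_min: float = 60.0,
    min_sleep_min: float = 180.0,
) -> List[SleepNight]:
    """Split sleep-typed minutes into nights.

    Consecutive sleep minutes whose gap is <= ``bridge_min`` minutes
    belong to one run; runs with fewer than ``min_sleep_min`` sleep
    minutes are flagged invalid (kept in the output, excluded from
    summaries).  Gap minutes bridged into a run are not counted as
    sleep.
    """
    df = wristband.records
    if df.empty:
        return []
    mask = (df["ts"] >= period[0]) & (df["ts"] < period[1]) & df["type"].isin(SLEEP_TYPES)
    sleep = df.loc[mask].sort_values("ts").reset_index(drop=True)
    if sleep.empty:
        return []
    gaps = sleep["ts"].diff().dt.total_seconds().fillna(0.0) / 60.0
    run_id = (gaps > bridge_min).cumsum()
    nights: List[SleepNight] = []
    for _, run in sleep.groupby(run_id):
        onset = run["ts"].iloc[0]
        wake = run["ts"].iloc[-1] + pd.Timedelta(minutes=1)
        light = int((run["type"] == "light_sleep").sum())
        deep = int((run["type"] == "deep_sleep").sum())
        hr = run.loc[run["heart_rate"].notna(), ["ts", "heart_rate"]].copy()
        nights.append(
            SleepNight(
                date=onset.normalize(),
                onset=onset,
                wake=wake,
                light_min=light,
                deep_min=deep,
                valid=(light + deep) >= min_sleep_min,
                hr_points=hr,
            )
        )
    return nights


def sleep_features(nights: Sequence[SleepNight]) -> Dict[str, float]:
    """Average/median/SD of light, deep and total sleep minutes over
    valid nights, mean light/total and deep/total ratios, and circular
    means of sleep-onset and wake clock times."""
    valid = [n for n in nights if n.valid]
    names = {}
    if not valid:
        for part in ("light", "deep", "total"):
            for stat in ("mean", "median", "sd"):
                names[f"sleep.{part}_min_{stat}"] = float("nan")
        names.update({
            "sleep.light_ratio": float("nan"),
            "sleep.deep_ratio": float("nan"),
            "sleep.onset_circmean": float("nan"),
            "sleep.wake_circmean": float("nan"),
            "sleep.n_nights": 0.0,
        })
        return names
    out: Dict[str, float] = {"sleep.n_nights": float(len(valid))}
    for part, values in (
        ("light", [n.light_min for n in valid]),
        ("deep", [n.deep_min for n in valid]),
        ("total", [n.total_min for n in valid]),
    ):
        s = pd.Series(values, dtype=float)
        out[f"sleep.{part}_min_mean"] = float(s.mean())
        out[f"sleep.{part}_min_median"] = float(s.median())
        out[f"sleep.{part}_min_sd"] = float(s.std(ddof=1))
    ratios_light = [n.light_min / n.total_min for n in valid if n.total_min > 0]
    ratios_deep = [n.deep_min / n.total_min for n in valid if n.total_min > 0]
    out["sleep.light_ratio"] = float(np.mean(ratios_light)) if ratios_light else float("nan")
    out["sleep.deep_ratio"] = float(np.mean(ratios_deep)) if ratios_deep else float("nan")
    onset_hours = [n.onset.hour + n.onset.minute / 60.0 for n in valid]
    wake_hours = [n.wake.hour + n.wake.minute / 60.0 for n in valid]
    out["sleep.onset_circmean"] = circular_mean(onset_hours)
    out["sleep.wake_circmean"] = circular_mean(wake_hours)
    return out


def step_features(wristband: EventStream, period: Period) -> Dict[str, float]:
    """Step-count features: period total, daily-total summaries, and
    daily-total summaries within each of the eight 3-hour bins.

    Only days with at least one worn packet enter the per-day
    summaries; within such a day an empty bin contributes a true zero.
    """
    df = wristband.records
    out: Dict[str, float] = {}
    if not df.empty:
        mask = (df["ts"] >= period[0]) & (df["ts"] < period[1]) & df["type"].isin(WORN_TYPES)
        df = df.loc[mask]
    if df.empty:
        out["steps.total"] = 0.0
        for stat in ("mean", "median", "sd"):
            out[f"steps.daily_{stat}"] = float("nan")
        for k in range(8):
            for stat in ("mean", "median", "sd"):
                out[f"steps.bin{k}_daily_{stat}"] = float("nan")
        return out
    day = df["ts"].dt.normalize()
    daily = df.groupby(day)["steps"].sum().astype(float)
    out["steps.total"] = float(daily.sum())
    out["steps.daily_mean"] = float(daily.mean())
    out["steps.daily_median"] = float(daily.median())
    out["steps.daily_sd"] = float(daily.std(ddof=1))
    hours = _clock_hours(df["ts"])
    bin_idx = np.clip((hours // 3).astype(int), 0, 7)
    frame = pd.DataFrame({"day": day.values, "bin": bin_idx, "steps": df["steps"].values})
    pivot = frame.pivot_table(index="day", columns="bin", values="steps",
                              aggfunc="sum", fill_value=0.0)
    for k in range(8):
        col = pivot[k] if k in pivot.columns else pd.Series(0.0, index=pivot.index)
        out[f"steps.bin{k}_daily_mean"] = float(col.mean())
        out[f"steps.bin{k}_daily_median"] = float(col.median())
        out[f"steps.bin{k}_daily_sd"] = float(col.std(ddof=1))
    return out


def fit_cosinor(
    hours: Sequence[float],
    values: Sequence[float],
    period_h: float = 24.0,
    min_points: int = 10,
) -> Optional[CosinorFit]:
    """Least-squares cosinor fit via the linearization
    ``y = M + b1*cos(wt) + b2*sin(wt)`` with ``w = 2*pi/period_h``.

    Amplitude is ``hypot(b1, b2)`` and the acrophase solves
    ``b1 = A cos(w*phi)``, ``b2 = A sin(w*phi)`` mapped into
    ``[0, period_h)``.  Returns None with fewer than ``min_points``
    observations.  A zero-variance signal yields amplitude ~0 and, by
    convention, acrophase 0 and r2 = 0.
    """
    t = np.asarray(hours, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = ~(np.isnan(t) | np.isnan(y))
    t, y = t[keep], y[keep]
    n = t.size
    if n < min_points:
        return None
    w = 2.0 * np.pi / period_h
    design = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    mesor, b1, b2 = (float(b) for b in beta)
    amplitude = float(np.hypot(b1, b2))
    resid = y - design @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 1e-12:
        return CosinorFit(mesor=float(y.mean()), amplitude=0.0, acrophase=0.0,
                          r2=0.0, n_points=n)
    r2 = max(0.0, min(1.0, 1.0 - sse / sst))
    acrophase = float((np.arctan2(b2, b1) / w) % period_h)
    if acrophase >= period_h:  # tiny negative angles wrap to exactly period_h
        acrophase = 0.0
    return CosinorFit(mesor=mesor, amplitude=amplitude, acrophase=acrophase,
                      r2=r2, n_points=n)


def nightly_cosinor_fits(
    nights: Sequence[SleepNight],
    period_h: float = 24.0,
    min_points: int = 10,
) -> List[CosinorFit]:
    """One cosinor fit per valid night with enough heart-rate minutes."""
    fits: List[CosinorFit] = []
    for night in nights:
        if not night.valid or len(night.hr_points) < min_points:
            continue
        hours = _clock_hours(night.hr_points["ts"])
        fit = fit_cosinor(hours, night.hr_points["heart_rate"].to_numpy(float),
                          period_h=period_h, min_points=min_points)
        if fit is not None:
            fits.append(fit)
    return fits


def heart_rate_features(fits: Sequence[CosinorFit]) -> Dict[str, float]:
    """Across-night summaries of the four cosinor parameters.

    Mesor, amplitude and r2 get mean/median/SD; acrophase, being a clock
    value, gets circular mean/median/SD.
    """
    out: Dict[str, float] = {"hr.n_fits": float(len(fits))}
    if not fits:
        for base in ("mesor", "amplitude", "r2"):
            for stat in ("mean", "median", "sd"):
                out[f"hr.{base}_{stat}"] = float("nan")
        for stat in ("circmean", "circmedian", "circsd"):
            out[f"hr.acrophase_{stat}"] = float("nan")
        return out
    for base, values in (
        ("mesor", [f.mesor for f in fits]),
        ("amplitude", [f.amplitude for f in fits]),
        ("r2", [f.r2 for f in fits]),
    ):
        s = pd.Series(values, dtype=float)
        out[f"hr.{base}_mean"] = float(s.mean())
        out[f"hr.{base}_median"] = float(s.median())
        out[f"hr.{base}_sd"] = float(s.std(ddof=1))
    acro = [f.acrophase for f in fits]
    out["hr.acrophase_circmean"] = circular_mean(acro)
    out["hr.acrophase_circmedian"] = circular_median(acro)
    # n=1 gives NaN spread, matching the linear-SD (ddof=1) convention
    out["hr.acrophase_circsd"] = circular_sd(acro) if len(acro) > 1 else float("nan")
    return out
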