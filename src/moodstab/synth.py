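"""Synthetic participant-level raw streams and PHQ-9 trajectories.

Every downstream stage is testable without real data: the generator
emits the same JSON-lines schemas the ingest module reads, with a
configurable coupling between a latent mood trajectory and behavioral
rates.  Event times are drawn from inhomogeneous Poisson processes with
clock-time intensity profiles; Swing scenarios apply a multiplicative
regime shift to second-period rates at a single changepoint (the middle
PHQ-9 time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .ingest import (
    CALL_DIRECTIONS,
    EventStream,
    Phq9Record,
    REAL_APP_CATEGORIES,
    STREAM_FILES,
)

__all__ = [
    "SCENARIOS",
    "ParticipantProfile",
    "TrajectorySpec",
    "draw_phq9_scores",
    "generate_participant",
    "generate_cohort",
    "iter_cohort",
    "write_participant",
    "default_profile",
]

SCENARIOS = (
    "steady_remission",
    "steady_depressed",
    "swing_drastic",
    "swing_moderate",
    "null_effect",
)

#: relative clock-time intensity of daytime phone/step activity
_HOUR_WEIGHTS = np.array(
    [0.05, 0.02, 0.02, 0.02, 0.02, 0.05, 0.30, 0.60,
     1.00, 1.00, 1.00, 1.00, 1.20, 1.00, 1.00, 1.00,
     1.00, 1.00, 1.20, 1.20, 1.00, 0.80, 0.50, 0.20]
)

_APP_IDS = {cat: [f"{cat}.app{j}" for j in range(3)] for cat in REAL_APP_CATEGORIES}


@dataclass
class ParticipantProfile:
    """Baseline behavioral rates and device-compliance of one synthetic
    participant."""

    participant_id: str
    call_rates: Mapping[str, float] = field(
        default_factory=lambda: {"incoming": 3.0, "outgoing": 3.0, "rejected": 0.5}
    )
    screen_sessions_per_day: float = 25.0
    app_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "instant_messaging": 12.0,
            "social_networking": 5.0,
            "shopping": 1.5,
            "entertainment": 4.0,
            "music": 1.5,
            "food_delivery": 0.8,
            "others": 3.0,
        }
    )
    mean_daily_steps: float = 7000.0
    sleep_onset_hour: float = 23.25   # local clock hours, may exceed 24
    wake_hour: float = 7.0
    deep_sleep_fraction: float = 0.3
    hr_mesor: float = 62.0
    hr_amplitude: float = 6.0
    hr_acrophase: float = 4.0         # hours in [0, 24)
    compliance: Mapping[str, float] = field(
        default_factory=lambda: {"call": 0.95, "screen": 0.95, "app": 0.95,
                                 "wristband": 0.9}
    )
    n_peers: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in {**dict(self.call_rates), **dict(self.app_rates),
                           "screen": self.screen_sessions_per_day,
                           "steps": self.mean_daily_steps}.items():
            if rate < 0:
                raise ValueError(f"rate {name} must be >= 0")
        if not 0.0 <= self.deep_sleep_fraction <= 1.0:
            raise ValueError("deep_sleep_fraction must lie in [0, 1]")
        if self.hr_amplitude < 0:
            raise ValueError("hr_amplitude must be >= 0")
        if not 0.0 <= self.hr_acrophase < 24.0:
            raise ValueError("hr_acrophase must lie in [0, 24)")
        for kind, p in dict(self.compliance).items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"compliance[{kind}] must lie in [0, 1]")


@dataclass
class TrajectorySpec:
    """Mood scenario and its behavioral coupling."""

    scenario: str
    phq9_times: Sequence[pd.Timestamp]
    effect_size: float = 1.5     # multiplicative rate shift in period 2
    hr_noise_sd: float = 2.0
    jitter_sd_h: float = 0.5     # nightly onset/wake jitter

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"invalid scenario {self.scenario!r}; "
                             f"expected one of {SCENARIOS}")
        times = list(self.phq9_times)
        if len(times) < 2:
            raise ValueError("need at least two PHQ-9 times")
        for a, b in zip(times, times[1:]):
            if b <= a:
                raise ValueError("phq9_times must be strictly increasing")


def draw_phq9_scores(scenario: str, n: int, rng: np.random.Generator) -> List[int]:
    """Integer PHQ-9 totals such that *every* consecutive triple
    satisfies the scenario's label criterion.

    Steady scenarios draw i.i.d. scores from the allowed set; swing
    scenarios alternate a low and a high level so each triple contains
    both extremes.  ``null_effect`` borrows the score pattern of a
    random labeled scenario (behavior carries no shift regardless).
    """
    if scenario == "null_effect":
        scenario = SCENARIOS[rng.integers(0, 4)]
    if scenario == "steady_remission":
        # all <= 5 AND range < 5, else precedence would call it a swing
        while True:
            scores = rng.integers(0, 6, size=n)
            if scores.max() - scores.min() < 5:
                return [int(s) for s in scores]
    if scenario == "steady_depressed":
        base = int(rng.integers(11, 24))
        return [int(s) for s in rng.integers(base, min(base + 5, 28), size=n)]
    if scenario == "swing_drastic":
        low = int(rng.integers(0, 18))
        high = int(rng.integers(low + 10, 28))
    elif scenario == "swing_moderate":
        low = int(rng.integers(0, 23))
        high = int(rng.integers(low + 5, min(low + 10, 28)))
    else:  # pragma: no cover
        raise ValueError(scenario)
    start_high = bool(rng.integers(0, 2))
    return [high if (i % 2 == 0) == start_high else low for i in range(n)]


def _zipf_probs(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def _draw_event_times(
    day: pd.Timestamp, n: int, rng: np.random.Generator
) -> List[pd.Timestamp]:
    if n == 0:
        return []
    hours = rng.choice(24, size=n, p=_HOUR_WEIGHTS / _HOUR_WEIGHTS.sum())
    frac = rng.uniform(0, 1, size=n)
    offsets = np.sort(hours + frac)
    return [day + pd.Timedelta(hours=float(h)) for h in offsets]


def generate_participant(
    profile: ParticipantProfile,
    spec: TrajectorySpec,
) -> Tuple[Dict[str, EventStream], List[Phq9Record]]:
    """Generate all five streams of one participant.

    Wristband packets are one per minute within wear bouts; heart rate
    is present only on light/deep sleep minutes and follows
    ``mesor + amplitude*cos(2*pi*(t - acrophase)/24)`` plus Gaussian
    noise.  Swing scenarios multiply second-period behavioral rates by
    ``effect_size`` (sleep duration, deep fraction and HR amplitude are
    divided by it).
    """
    rng = np.random.default_rng(profile.seed)
    times = [pd.Timestamp(t) for t in spec.phq9_times]
    tz = times[0].tz
    if tz is None:
        raise ValueError("phq9_times must be timezone-aware")

    scores = draw_phq9_scores(spec.scenario, len(times), rng)
    phq9 = [Phq9Record(ts=t, score=s) for t, s in zip(times, scores)]

    changepoint = times[len(times) // 2].normalize()
    is_swing = spec.scenario.startswith("swing")
    day0 = times[0].normalize()
    day_last = times[-1].normalize()
    days = pd.date_range(day0, day_last, freq="D", tz=tz)

    peer_probs = _zipf_probs(profile.n_peers)
    peers = [f"{profile.participant_id}-peer{j:03d}" for j in range(profile.n_peers)]

    calls: List[dict] = []
    screen: List[dict] = []
    apps: List[dict] = []

    def factor(day: pd.Timestamp) -> float:
        return spec.effect_size if is_swing and day >= changepoint else 1.0

    for day in days:
        f = factor(day)
        # --- call log ---
        if rng.uniform() < profile.compliance.get("call", 1.0):
            for direction in CALL_DIRECTIONS:
                n = rng.poisson(profile.call_rates.get(direction, 0.0) * f)
                for ts in _draw_event_times(day, n, rng):
                    dur = 0.0 if direction == "rejected" else round(
                        float(rng.exponential(180.0)), 1)
                    peer = peers[rng.choice(profile.n_peers, p=peer_probs)]
                    calls.append({"ts": ts, "direction": direction,
                                  "duration_s": dur, "peer": peer})
        # --- screen sessions ---
        if rng.uniform() < profile.compliance.get("screen", 1.0):
            n = rng.poisson(profile.screen_sessions_per_day * f)
            last_end = None
            for ts in _draw_event_times(day, n, rng):
                if last_end is not None and ts < last_end:
                    continue  # drop overlapping sessions
                dur = pd.Timedelta(seconds=float(rng.lognormal(5.0, 1.0)))
                screen.append({"ts": ts, "event": "on"})
                screen.append({"ts": ts + dur, "event": "off"})
                last_end = ts + dur
        # --- app sessions ---
        if rng.uniform() < profile.compliance.get("app", 1.0):
            for cat in REAL_APP_CATEGORIES:
                n = rng.poisson(profile.app_rates.get(cat, 0.0) * f)
                for ts in _draw_event_times(day, n, rng):
                    dur = pd.Timedelta(seconds=float(rng.lognormal(5.5, 1.0)))
                    app_id = _APP_IDS[cat][rng.integers(0, len(_APP_IDS[cat]))]
                    apps.append({"ts_start": ts, "ts_end": ts + dur,
                                 "app_id": app_id, "category": cat})

    wristband = _generate_wristband(profile, spec, days, factor, rng)

    calls_df = pd.DataFrame(calls).sort_values("ts", kind="stable").reset_index(drop=True) \
        if calls else pd.DataFrame()
    screen_df = pd.DataFrame(screen).sort_values("ts", kind="stable").reset_index(drop=True) \
        if screen else pd.DataFrame()
    apps_df = pd.DataFrame(apps).sort_values("ts_start", kind="stable").reset_index(drop=True) \
        if apps else pd.DataFrame()
    phq9_df = pd.DataFrame({"ts": times, "score": scores})

    pid = profile.participant_id
    streams = {
        "call": EventStream(pid, "call", calls_df),
        "screen": EventStream(pid, "screen", screen_df),
        "app": EventStream(pid, "app", apps_df),
        "wristband": EventStream(pid, "wristband", wristband),
        "phq9": EventStream(pid, "phq9", phq9_df),
    }
    return streams, phq9


def _generate_wristband(
    profile: ParticipantProfile,
    spec: TrajectorySpec,
    days: pd.DatetimeIndex,
    factor,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Minute packets: nightly sleep runs plus daytime wear with a random
    not-worn gap.  Whole days are dropped with prob 1 - compliance."""
    ts_all: List[pd.Timestamp] = []
    type_all: List[str] = []
    intensity_all: List[float] = []
    steps_all: List[int] = []
    hr_all: List[float] = []
    w = 2.0 * np.pi / 24.0
    compliance = profile.compliance.get("wristband", 1.0)

    prev_wake = days[0] + pd.Timedelta(hours=profile.wake_hour)
    for day in days:
        worn_day = rng.uniform() < compliance
        f = factor(day)
        onset = day + pd.Timedelta(
            hours=profile.sleep_onset_hour + float(rng.normal(0, spec.jitter_sd_h)))
        wake = day + pd.Timedelta(days=1) + pd.Timedelta(
            hours=profile.wake_hour + float(rng.normal(0, spec.jitter_sd_h)))
        # shorter sleep and shallower architecture under an activating shift
        sleep_span = (wake - onset) / f
        wake = onset + sleep_span
        deep_frac = min(max(profile.deep_sleep_fraction / f, 0.02), 0.95)

        if worn_day:
            # daytime block: previous wake -> tonight's onset, with one gap
            day_start = max(prev_wake, day)
            day_minutes = pd.date_range(day_start.ceil("min"), onset, freq="min",
                                        inclusive="left")
            if len(day_minutes):
                gap_len = float(rng.uniform(60, 180))
                gap_pos = float(rng.uniform(0, max(1.0, len(day_minutes) - gap_len)))
                gap_lo, gap_hi = int(gap_pos), int(gap_pos + gap_len)
                hours = (day_minutes.hour + day_minutes.minute / 60.0).to_numpy()
                weights = _HOUR_WEIGHTS[day_minutes.hour.to_numpy()]
                lam = profile.mean_daily_steps * f * weights / weights.sum() \
                    if weights.sum() > 0 else np.zeros(len(day_minutes))
                steps = rng.poisson(lam)
                intensity = np.round(rng.gamma(2.0, 5.0, size=len(day_minutes)), 2)
                for i, ts in enumerate(day_minutes):
                    in_gap = gap_lo <= i < gap_hi
                    ts_all.append(ts)
                    type_all.append("not_worn" if in_gap else "activity")
                    intensity_all.append(0.0 if in_gap else float(intensity[i]))
                    steps_all.append(0 if in_gap else int(steps[i]))
                    hr_all.append(float("nan"))
            # night block: onset -> wake
            night_minutes = pd.date_range(onset.ceil("min"), wake, freq="min",
                                          inclusive="left")
            if len(night_minutes):
                deep = rng.uniform(size=len(night_minutes)) < deep_frac
                hours = (night_minutes.hour + night_minutes.minute / 60.0).to_numpy()
                hr = (profile.hr_mesor
                      + (profile.hr_amplitude / f)
                      * np.cos(w * (hours - profile.hr_acrophase))
                      + rng.normal(0, spec.hr_noise_sd, size=len(night_minutes)))
                hr = np.round(hr, 2)
                for i, ts in enumerate(night_minutes):
                    ts_all.append(ts)
                    type_all.append("deep_sleep" if deep[i] else "light_sleep")
                    intensity_all.append(0.0)
                    steps_all.append(0)
                    hr_all.append(float(hr[i]))
        prev_wake = wake

    if not ts_all:
        return pd.DataFrame()
    df = pd.DataFrame({
        "ts": ts_all,
        "type": type_all,
        "intensity": intensity_all,
        "steps": steps_all,
        "heart_rate": hr_all,
    })
    return df.sort_values("ts", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# serialization and cohort generation
# ---------------------------------------------------------------------------

def _fmt_ts(ts: pd.Timestamp) -> str:
    return ts.isoformat()


def write_participant(
    directory: str | Path,
    streams: Mapping[str, EventStream],
    phq9: Sequence[Phq9Record],
) -> None:
    """Write one participant's streams as the canonical JSON-lines files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def dump(path: Path, rows: List[str]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(rows) + ("\n" if rows else ""))

    df = streams["call"].records
    rows = [
        json.dumps({"ts": _fmt_ts(r.ts), "direction": r.direction,
                    "duration_s": r.duration_s, "peer": r.peer})
        for r in df.itertuples()
    ] if not df.empty else []
    dump(directory / STREAM_FILES["call"], rows)

    df = streams["screen"].records
    rows = [
        json.dumps({"ts": _fmt_ts(r.ts), "event": r.event})
        for r in df.itertuples()
    ] if not df.empty else []
    dump(directory / STREAM_FILES["screen"], rows)

    df = streams["app"].records
    rows = [
        json.dumps({"ts_start": _fmt_ts(r.ts_start), "ts_end": _fmt_ts(r.ts_end),
                    "app_id": r.app_id, "category": r.category})
        for r in df.itertuples()
    ] if not df.empty else []
    dump(directory / STREAM_FILES["app"], rows)

    df = streams["wristband"].records
    rows = []
    if not df.empty:
        for r in df.itertuples():
            hr = None if pd.isna(r.heart_rate) else r.heart_rate
            rows.append(json.dumps({
                "ts": _fmt_ts(r.ts), "type": r.type, "intensity": r.intensity,
                "steps": int(r.steps), "heart_rate": hr,
            }))
    dump(directory / STREAM_FILES["wristband"], rows)

    rows = [json.dumps({"ts": _fmt_ts(rec.ts), "score": rec.score}) for rec in phq9]
    dump(directory / STREAM_FILES["phq9"], rows)


def default_profile(
    participant_id: str,
    seed: int,
    rng: np.random.Generator,
) -> ParticipantProfile:
    """Per-participant baseline rates drawn around population means."""
    return ParticipantProfile(
        participant_id=participant_id,
        call_rates={
            "incoming": float(rng.uniform(1.5, 5.0)),
            "outgoing": float(rng.uniform(1.5, 5.0)),
            "rejected": float(rng.uniform(0.1, 1.0)),
        },
        screen_sessions_per_day=float(rng.uniform(15, 40)),
        app_rates={
            "instant_messaging": float(rng.uniform(6, 18)),
            "social_networking": float(rng.uniform(2, 8)),
            "shopping": float(rng.uniform(0.5, 3)),
            "entertainment": float(rng.uniform(2, 6)),
            "music": float(rng.uniform(0.5, 3)),
            "food_delivery": float(rng.uniform(0.2, 1.5)),
            "others": float(rng.uniform(1, 5)),
        },
        mean_daily_steps=float(rng.uniform(4000, 10000)),
        sleep_onset_hour=float(rng.uniform(22.0, 24.5)),
        wake_hour=float(rng.uniform(6.0, 8.5)),
        deep_sleep_fraction=float(rng.uniform(0.2, 0.4)),
        hr_mesor=float(rng.uniform(55, 70)),
        hr_amplitude=float(rng.uniform(4, 9)),
        hr_acrophase=float(rng.uniform(2, 6)),
        n_peers=int(rng.integers(6, 20)),
        seed=seed,
    )


def _phq9_schedule(
    start: pd.Timestamp,
    n_times: int,
    gap_days: float,
    jitter_days: float,
    rng: np.random.Generator,
) -> List[pd.Timestamp]:
    times = [start]
    for _ in range(n_times - 1):
        gap = gap_days + float(rng.uniform(-jitter_days, jitter_days))
        times.append(times[-1] + pd.Timedelta(days=max(gap, 7.5)))
    return times


def iter_cohort(
    n_per_scenario: int,
    seed: int,
    scenarios: Sequence[str] = SCENARIOS,
    start: str = "2024-03-04T09:00:00+08:00",
    n_phq9: int = 3,
    gap_days: float = 14.0,
    jitter_days: float = 2.0,
    effect_size: float = 1.5,
    hr_noise_sd: float = 2.0,
    scenario_weights: Mapping[str, int] | None = None,
):
    """Yield ``(profile, spec, streams, phq9)`` for a reproducible cohort.

    ``scenario_weights`` overrides the per-scenario count (useful for
    deliberately imbalanced cohorts).
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    master = np.random.default_rng(seed)
    start_ts = pd.Timestamp(start)
    idx = 0
    for scenario in scenarios:
        n_this = (scenario_weights or {}).get(scenario, n_per_scenario)
        for _ in range(n_this):
            sub_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sub_seed)
            pid = f"p{idx:04d}_{scenario}"
            profile = default_profile(pid, seed=sub_seed + 1, rng=rng)
            times = _phq9_schedule(start_ts, n_phq9, gap_days, jitter_days, rng)
            spec = TrajectorySpec(scenario=scenario, phq9_times=times,
                                  effect_size=effect_size, hr_noise_sd=hr_noise_sd)
            streams, phq9 = generate_participant(profile, spec)
            yield profile, spec, streams, phq9
            idx += 1


def generate_cohort(
    n_per_scenario: int,
    seed: int,
    out_dir: str | Path,
    **kwargs,
) -> Path:
    """Write a full cohort (one sub-directory per participant) plus a
    manifest; byte-identical across runs with the same arguments."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "n_per_scenario": n_per_scenario, "participants": []}
    for profile, spec, streams, phq9 in iter_cohort(n_per_scenario, seed, **kwargs):
        pdir = out_dir / profile.participant_id
        write_participant(pdir, streams, phq9)
        manifest["participants"].append({
            "participant_id": profile.participant_id,
            "scenario": spec.scenario,
            "n_phq9": len(phq9),
        })
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir
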