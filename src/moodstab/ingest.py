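"""Reading and validating raw event streams.

All streams are JSON-lines files, one record per line, timestamps
ISO-8601 with timezone.  At load time every timestamp is converted to a
single participant-local timezone, because all downstream clock-time
bins (e.g. "6 AM to noon") are defined in local time.

Stream kinds and their record schemas:

=========  =============================================================
calls      {ts, direction: incoming|outgoing|rejected, duration_s, peer}
screen     {ts, event: on|off}
apps       {ts_start, ts_end, app_id, category}
wristband  {ts, type: activity|light_sleep|deep_sleep|not_worn,
            intensity, steps, heart_rate (null unless a sleep type)}
phq9       {ts, score: int 0..27}
=========  =============================================================
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "APP_CATEGORIES",
    "WORN_TYPES",
    "SLEEP_TYPES",
    "CALL_DIRECTIONS",
    "EventStream",
    "Phq9Record",
    "IngestError",
    "load_participant",
    "load_phq9",
    "clean_screen_events",
]

CALL_DIRECTIONS = ("incoming", "outgoing", "rejected")
SLEEP_TYPES = ("light_sleep", "deep_sleep")
WORN_TYPES = ("activity", "light_sleep", "deep_sleep")
WRISTBAND_TYPES = WORN_TYPES + ("not_worn",)

#: the eight app categories; "all_apps" is the aggregate pseudo-category
APP_CATEGORIES = (
    "instant_messaging",
    "social_networking",
    "shopping",
    "entertainment",
    "music",
    "food_delivery",
    "others",
    "all_apps",
)
REAL_APP_CATEGORIES = tuple(c for c in APP_CATEGORIES if c != "all_apps")

STREAM_FILES = {
    "call": "calls.jsonl",
    "screen": "screen.jsonl",
    "app": "apps.jsonl",
    "wristband": "wristband.jsonl",
    "phq9": "phq9.jsonl",
}

_TS_FIELDS = {
    "call": ("ts",),
    "screen": ("ts",),
    "app": ("ts_start", "ts_end"),
    "wristband": ("ts",),
    "phq9": ("ts",),
}


class IngestError(RuntimeError):
    """Raised when a stream file's malformed-line rate exceeds the
    configured threshold."""


@dataclass
class Phq9Record:
    ts: pd.Timestamp
    score: int

    def __post_init__(self) -> None:
        if not 0 <= int(self.score) <= 27:
            raise ValueError(f"PHQ-9 score out of range: {self.score}")
        self.score = int(self.score)


@dataclass
class EventStream:
    """Time-ordered records of one kind for one participant."""

    participant_id: str
    kind: str
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.kind not in STREAM_FILES:
            raise ValueError(f"unknown stream kind: {self.kind}")

    def __len__(self) -> int:
        return len(self.records)


def _validate_record(kind: str, rec: dict) -> dict:
    if kind == "call":
        if rec["direction"] not in CALL_DIRECTIONS:
            raise ValueError("bad direction")
        if float(rec["duration_s"]) < 0:
            raise ValueError("negative duration")
        str(rec["peer"])
    elif kind == "screen":
        if rec["event"] not in ("on", "off"):
            raise ValueError("bad screen event")
    elif kind == "app":
        if rec["category"] not in APP_CATEGORIES:
            # unknown categories are coerced, not rejected
            logger.warning("unknown app category %r assigned to 'others'", rec["category"])
            rec["category"] = "others"
        str(rec["app_id"])
    elif kind == "wristband":
        if rec["type"] not in WRISTBAND_TYPES:
            raise ValueError("bad wristband type")
        if float(rec["intensity"]) < 0 or int(rec["steps"]) < 0:
            raise ValueError("negative intensity/steps")
        hr = rec.get("heart_rate")
        if hr is not None and rec["type"] not in SLEEP_TYPES:
            raise ValueError("heart_rate present outside sleep")
    elif kind == "phq9":
        if not 0 <= int(rec["score"]) <= 27:
            raise ValueError("PHQ-9 score out of range")
    return rec


def _read_jsonl(
    path: Path,
    kind: str,
    tz: str,
    max_reject_rate: float,
) -> pd.DataFrame:
    records: List[dict] = []
    n_bad = 0
    first_bad: Optional[int] = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = _validate_record(kind, json.loads(line))
                for f in _TS_FIELDS[kind]:
                    rec[f] = pd.Timestamp(rec[f])
                    if rec[f].tzinfo is None:
                        raise ValueError("naive timestamp")
                records.append(rec)
            except (ValueError, KeyError, TypeError, json.JSONDecodeError):
                n_bad += 1
                if first_bad is None:
                    first_bad = lineno
    n_total = len(records) + n_bad
    if n_bad:
        logger.warning("%s: rejected %d of %d lines (first at line %s)",
                       path.name, n_bad, n_total, first_bad)
    if n_total and n_bad / n_total > max_reject_rate:
        raise IngestError(
            f"{path}: {n_bad}/{n_total} malformed lines exceeds threshold "
            f"{max_reject_rate:.0%} (first bad line: {first_bad})"
        )
    df = pd.DataFrame(records)
    if not df.empty:
        for f in _TS_FIELDS[kind]:
            df[f] = pd.to_datetime(df[f], utc=True).dt.tz_convert(tz)
        sort_key = _TS_FIELDS[kind][0]
        df = df.sort_values(sort_key, kind="stable").reset_index(drop=True)
    return df


def load_participant(
    directory: str | Path,
    participant_id: str,
    tz: str = "Asia/Shanghai",
    max_reject_rate: float = 0.05,
) -> Dict[str, EventStream]:
    """Load every stream of one participant from ``directory``.

    Missing files yield empty streams of that kind.  Malformed lines are
    counted and logged; the load hard-fails only when a file's rejection
    rate exceeds ``max_reject_rate``.  Screen streams are cleaned into
    strictly alternating on/off pairs.
    """
    directory = Path(directory)
    streams: Dict[str, EventStream] = {}
    for kind, fname in STREAM_FILES.items():
        path = directory / fname
        if path.exists():
            df = _read_jsonl(path, kind, tz, max_reject_rate)
        else:
            df = pd.DataFrame()
        stream = EventStream(participant_id, kind, df)
        if kind == "screen":
            stream = clean_screen_events(stream)
        streams[kind] = stream
    return streams


def load_phq9(streams: Dict[str, EventStream]) -> List[Phq9Record]:
    df = streams["phq9"].records
    if df.empty:
        return []
    return [Phq9Record(ts=row.ts, score=int(row.score)) for row in df.itertuples()]


def clean_screen_events(stream: EventStream) -> EventStream:
    """Repair a screen stream into strictly alternating on/off pairs.

    Consecutive duplicate events are collapsed keeping the first; a
    leading "off" and a trailing unmatched "on" are dropped.  Idempotent.
    """
    if stream.kind != "screen":
        raise ValueError("clean_screen_events requires a screen stream")
    df = stream.records
    if df.empty:
        return EventStream(stream.participant_id, "screen", df)
    keep_idx: List[int] = []
    expect = "on"
    for i, ev in enumerate(df["event"]):
        if ev == expect:
            keep_idx.append(i)
            expect = "off" if expect == "on" else "on"
    if keep_idx and df["event"].iloc[keep_idx[-1]] == "on":
        keep_idx.pop()
    out = df.iloc[keep_idx].reset_index(drop=True)
    return EventStream(stream.participant_id, "screen", out)


def screen_sessions(stream: EventStream) -> pd.DataFrame:
    """Pair cleaned on/off events into usage sessions (ts_start, ts_end)."""
    df = stream.records
    if df.empty:
        return pd.DataFrame(columns=["ts_start", "ts_end"])
    ons = df.loc[df["event"] == "on", "ts"].reset_index(drop=True)
    offs = df.loc[df["event"] == "off", "ts"].reset_index(drop=True)
    n = min(len(ons), len(offs))
    return pd.DataFrame({"ts_start": ons.iloc[:n], "ts_end": offs.iloc[:n]})
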