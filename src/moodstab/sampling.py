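"""Two-period sample construction and mood-stability labeling.

A *sample* is the span between three consecutive PHQ-9 submissions,
split at the middle submission into two periods.  Samples are labeled
Steady (remission / depressed) or Swing (drastic / moderate) from the
three total scores, and discarded when either period is shorter than one
week or a stream has fewer than three effective days in either period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .ingest import EventStream, Phq9Record, WORN_TYPES

__all__ = [
    "LABELS",
    "STEADY_LABELS",
    "SWING_LABELS",
    "DataSample",
    "assign_label",
    "make_samples",
    "effective_days",
    "build_samples",
    "samples_to_frame",
]

STEADY_LABELS = ("steady_remission", "steady_depressed")
SWING_LABELS = ("swing_drastic", "swing_moderate")
LABELS = STEADY_LABELS + SWING_LABELS + ("unlabeled",)

#: streams whose effective-day counts gate sample retention
GATED_KINDS = ("call", "screen", "app", "wristband")


def assign_label(s1: int, s2: int, s3: int) -> str:
    """Label a PHQ-9 score triple.

    Precedence: swing_drastic (range >= 10), then swing_moderate
    (range >= 5), then steady_remission (all <= 5), then
    steady_depressed (all >= 11 and range < 5); anything else is
    ``"unlabeled"``.  The swing-first precedence makes the four classes
    disjoint: moderate effectively means 5 <= range < 10.
    """
    scores = (s1, s2, s3)
    for s in scores:
        if not isinstance(s, (int,)) or isinstance(s, bool):
            if not float(s).is_integer():
                raise ValueError(f"PHQ-9 score must be an integer, got {s!r}")
        if not 0 <= s <= 27:
            raise ValueError(f"PHQ-9 score out of range [0, 27]: {s}")
    rng = max(scores) - min(scores)
    if rng >= 10:
        return "swing_drastic"
    if rng >= 5:
        return "swing_moderate"
    if max(scores) <= 5:
        return "steady_remission"
    if min(scores) >= 11:  # range < 5 is already guaranteed here
        return "steady_depressed"
    return "unlabeled"


@dataclass
class DataSample:
    """One labeled two-period sample for one participant."""

    participant_id: str
    phq9_triple: Tuple[Phq9Record, Phq9Record, Phq9Record]
    label: str
    #: per stream kind -> (effective days in period 1, in period 2)
    effective: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    @property
    def t1(self) -> pd.Timestamp:
        return self.phq9_triple[0].ts

    @property
    def t2(self) -> pd.Timestamp:
        return self.phq9_triple[1].ts

    @property
    def t3(self) -> pd.Timestamp:
        return self.phq9_triple[2].ts

    @property
    def scores(self) -> Tuple[int, int, int]:
        return tuple(r.score for r in self.phq9_triple)  # type: ignore[return-value]

    @property
    def period1(self) -> Tuple[pd.Timestamp, pd.Timestamp]:
        return (self.t1, self.t2)

    @property
    def period2(self) -> Tuple[pd.Timestamp, pd.Timestamp]:
        return (self.t2, self.t3)

    def usable_for(self, kinds: Sequence[str], min_days: int = 3) -> bool:
        """True if every stream kind has >= min_days effective days in
        both periods (the per-data-type-combination discard rule)."""
        for kind in kinds:
            n1, n2 = self.effective.get(kind, (0, 0))
            if n1 < min_days or n2 < min_days:
                return False
        return True


def make_samples(
    phq9: Sequence[Phq9Record],
    min_period_days: float = 7.0,
) -> List[Tuple[Phq9Record, Phq9Record, Phq9Record]]:
    """Sliding-window (stride 1) triples of consecutive PHQ-9 records,
    keeping only triples where both periods last >= ``min_period_days``.

    Fewer than three records yields an empty list.
    """
    records = sorted(phq9, key=lambda r: r.ts)
    out = []
    min_span = pd.Timedelta(days=min_period_days)
    for i in range(len(records) - 2):
        r1, r2, r3 = records[i], records[i + 1], records[i + 2]
        if (r2.ts - r1.ts) >= min_span and (r3.ts - r2.ts) >= min_span:
            out.append((r1, r2, r3))
    return out


def effective_days(
    stream: EventStream,
    period: Tuple[pd.Timestamp, pd.Timestamp],
    min_worn_minutes: int = 240,
) -> int:
    """Count local calendar days in ``period`` with effective data.

    Phone streams (call / screen / app / phq9): a day is effective if it
    holds at least one record.  Wristband: a day is effective if it has
    at least ``min_worn_minutes`` worn minute-packets (any type except
    "not_worn").
    """
    df = stream.records
    if df.empty:
        return 0
    ts_col = "ts_start" if stream.kind == "app" else "ts"
    ts = df[ts_col]
    mask = (ts >= period[0]) & (ts < period[1])
    sub = df.loc[mask]
    if sub.empty:
        return 0
    days = sub[ts_col].dt.normalize()
    if stream.kind == "wristband":
        worn = sub.loc[sub["type"].isin(WORN_TYPES), ts_col].dt.normalize()
        counts = worn.value_counts()
        return int((counts >= min_worn_minutes).sum())
    return int(days.nunique())


def build_samples(
    participant_id: str,
    streams: Dict[str, EventStream],
    phq9: Sequence[Phq9Record],
    min_period_days: float = 7.0,
    min_worn_minutes: int = 240,
) -> List[DataSample]:
    """Form, annotate and label every retained sample for one participant.

    Effective-day counts are recorded per stream kind and per period; the
    per-combination discard rule is applied later (``DataSample.usable_for``)
    because a sample can qualify for the sleep experiment but not the
    call-log one.
    """
    samples: List[DataSample] = []
    for triple in make_samples(phq9, min_period_days=min_period_days):
        label = assign_label(*(r.score for r in triple))
        eff: Dict[str, Tuple[int, int]] = {}
        p1 = (triple[0].ts, triple[1].ts)
        p2 = (triple[1].ts, triple[2].ts)
        for kind in GATED_KINDS:
            stream = streams.get(kind)
            if stream is None:
                eff[kind] = (0, 0)
            else:
                eff[kind] = (
                    effective_days(stream, p1, min_worn_minutes),
                    effective_days(stream, p2, min_worn_minutes),
                )
        samples.append(DataSample(participant_id, triple, label, eff))
    return samples


def samples_to_frame(samples: Sequence[DataSample]) -> pd.DataFrame:
    """Tabular view of samples (one row each), as written by the CLI."""
    rows = []
    counters: Dict[str, int] = {}
    for s in samples:
        i = counters.get(s.participant_id, 0)
        counters[s.participant_id] = i + 1
        row = {
            "sample_id": f"{s.participant_id}#{i}",
            "participant_id": s.participant_id,
            "t1": s.t1,
            "t2": s.t2,
            "t3": s.t3,
            "s1": s.scores[0],
            "s2": s.scores[1],
            "s3": s.scores[2],
            "label": s.label,
        }
        for kind in GATED_KINDS:
            n1, n2 = s.effective.get(kind, (0, 0))
            row[f"eff_{kind}_p1"] = n1
            row[f"eff_{kind}_p2"] = n2
        rows.append(row)
    return pd.DataFrame(rows)
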