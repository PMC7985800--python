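"""Clock-time binning of time intervals.

Sessions that span a bin boundary (including midnight) are split
proportionally, so the summed bin durations always equal the total
duration.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import pandas as pd

__all__ = ["clip_intervals", "seconds_in_daily_window", "THREE_HOUR_EDGES"]

#: the eight 3-hour bins: [0,3), [3,6), ... [21,24)
THREE_HOUR_EDGES: Tuple[Tuple[int, int], ...] = tuple((h, h + 3) for h in range(0, 24, 3))


def clip_intervals(
    df: pd.DataFrame,
    period: Tuple[pd.Timestamp, pd.Timestamp],
    start_col: str = "ts_start",
    end_col: str = "ts_end",
) -> pd.DataFrame:
    """Keep intervals intersecting ``period``, clipped to its bounds."""
    if df.empty:
        return df
    lo, hi = period
    mask = (df[end_col] > lo) & (df[start_col] < hi)
    out = df.loc[mask].copy()
    if out.empty:
        return out
    out[start_col] = out[start_col].clip(lower=lo)
    out[end_col] = out[end_col].clip(upper=hi)
    return out.reset_index(drop=True)


def seconds_in_daily_window(
    starts: Sequence[pd.Timestamp],
    ends: Sequence[pd.Timestamp],
    hour_lo: float,
    hour_hi: float,
) -> float:
    """Total seconds of the intervals falling in local clock window
    ``[hour_lo, hour_hi)``, accumulated over every day each interval
    touches."""
    total = 0.0
    lo_off = pd.Timedelta(hours=hour_lo)
    hi_off = pd.Timedelta(hours=hour_hi)
    one_day = pd.Timedelta(days=1)
    for s, e in zip(starts, ends):
        if e <= s:
            continue
        day = s.normalize()
        while day < e:
            w_lo = day + lo_off
            w_hi = day + hi_off
            overlap = (min(e, w_hi) - max(s, w_lo)).total_seconds()
            if overlap > 0:
                total += overlap
            day += one_day
    return total
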