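"""Feature extraction: per-period phone and wearable features, combined
across the two periods of each sample into difference / mean / SD
features."""

from __future__ import annotations

from typing import Dict, Mapping, Sequence, Tuple

import pandas as pd

from ..ingest import EventStream
from ..sampling import DataSample
from .aggregate import aggregate_periods
from .phone import app_features, call_features, screen_features
from .wearable import (
    CosinorFit,
    SleepNight,
    fit_cosinor,
    heart_rate_features,
    nightly_cosinor_fits,
    segment_nights,
    sleep_features,
    step_features,
)

Period = Tuple[pd.Timestamp, pd.Timestamp]

__all__ = [
    "call_features",
    "screen_features",
    "app_features",
    "segment_nights",
    "sleep_features",
    "step_features",
    "fit_cosinor",
    "nightly_cosinor_fits",
    "heart_rate_features",
    "aggregate_periods",
    "compute_period_features",
    "compute_sample_features",
    "extract_features",
    "build_manifest",
    "SleepNight",
    "CosinorFit",
]

#: feature-name prefix of every stream family, used by bench combos
FAMILY_PREFIXES = {
    "call": ("call.",),
    "screen": ("screen.",),
    "app": ("app.",),
    "sleep": ("sleep.",),
    "steps": ("steps.",),
    "hr": ("hr.",),
}


def compute_period_features(
    streams: Mapping[str, EventStream],
    period: Period,
    bridge_min: float = 60.0,
    min_sleep_min: float = 180.0,
    cosinor_period_h: float = 24.0,
    cosinor_min_points: int = 10,
) -> Dict[str, float]:
    """All per-period features for one period of one participant."""
    out: Dict[str, float] = {}
    out.update(call_features(streams["call"], period))
    out.update(screen_features(streams["screen"], period))
    out.update(app_features(streams["app"], period))
    nights = segment_nights(streams["wristband"], period,
                            bridge_min=bridge_min, min_sleep_min=min_sleep_min)
    out.update(sleep_features(nights))
    out.update(step_features(streams["wristband"], period))
    fits = nightly_cosinor_fits(nights, period_h=cosinor_period_h,
                                min_points=cosinor_min_points)
    out.update(heart_rate_features(fits))
    return out


def compute_sample_features(
    streams: Mapping[str, EventStream],
    sample: DataSample,
    **kwargs,
) -> Dict[str, float]:
    """Difference / mean / SD feature vector for one sample."""
    pf1 = compute_period_features(streams, sample.period1, **kwargs)
    pf2 = compute_period_features(streams, sample.period2, **kwargs)
    return aggregate_periods(pf1, pf2)


def extract_features(
    per_participant: Sequence[Tuple[Mapping[str, EventStream], Sequence[DataSample]]],
    **kwargs,
) -> pd.DataFrame:
    """Feature matrix over many participants' samples.

    ``per_participant`` is a sequence of (streams, samples) pairs.  The
    result has one row per sample, indexed by sample_id, with a
    ``label`` column and all feature columns.
    """
    rows = []
    index = []
    labels = []
    for streams, samples in per_participant:
        for i, sample in enumerate(samples):
            rows.append(compute_sample_features(streams, sample, **kwargs))
            index.append(f"{sample.participant_id}#{i}")
            labels.append(sample.label)
    df = pd.DataFrame(rows, index=index)
    df.insert(0, "label", labels)
    return df


_BIN_DESC = "3-hour clock bin {k} = [{lo:02d}:00, {hi:02d}:00) local time"


def build_manifest(feature_names: Sequence[str]) -> Dict[str, str]:
    """Human-readable description of every feature column."""
    out: Dict[str, str] = {}
    for name in feature_names:
        parts = name.split(".")
        agg = parts[-1] if parts[-1] in ("diff", "mean", "sd") else None
        base = ".".join(parts[:-1]) if agg else name
        desc = _describe_base(base)
        if agg:
            desc += {
                "diff": "; period2 minus period1",
                "mean": "; mean of the two periods",
                "sd": "; two-point sample SD |p2-p1|/sqrt(2)",
            }[agg]
        out[name] = desc
    return out


def _describe_base(base: str) -> str:
    stream = base.split(".")[0]
    if "bin" in base:
        import re

        m = re.search(r"bin(\d)", base)
        if m:
            k = int(m.group(1))
            return (f"{base}: per-period value restricted to "
                    + _BIN_DESC.format(k=k, lo=3 * k, hi=3 * k + 3))
    generic = {
        "call": "call-log feature (counts, durations, peers, entropy, call hour)",
        "screen": "screen on/off usage feature (daily counts/durations, clock-bin ratios)",
        "app": "app-usage feature per category (durations, counts, entropies, IM ratio)",
        "sleep": "sleep-architecture feature from wristband sleep minutes",
        "steps": "step-count feature from wristband minute packets",
        "hr": "nightly heart-rate cosinor parameter summary",
    }
    return f"{base}: {generic.get(stream, 'feature')}"
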