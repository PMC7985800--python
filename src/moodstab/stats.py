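"""Shared low-level statistics: Shannon entropy and circular summaries.

These primitives are used by every feature module.  Clock-valued
quantities (call hour, sleep onset, cosinor acrophase) live on a circle
of configurable period (24 h by default) and must never be averaged
linearly.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "entropy",
    "circular_mean",
    "circular_sd",
    "circular_median",
]


def entropy(counts: Mapping[object, float] | Iterable[float]) -> float:
    """Shannon entropy, in bits, of a discrete count distribution.

    Parameters
    ----------
    counts
        Mapping from event to a non-negative count (or weight), or a
        bare iterable of counts.  Probabilities are ``count / total``.

    Returns
    -------
    float
        ``-sum(p * log2(p))`` over events with positive count.  A single
        positive event yields 0.  If every count is zero the entropy has
        no basis and NaN is returned with a warning.
    """
    if isinstance(counts, Mapping):
        values = np.asarray(list(counts.values()), dtype=float)
    else:
        values = np.asarray(list(counts), dtype=float)
    if values.size and (values < 0).any():
        raise ValueError("counts must be non-negative")
    total = values.sum()
    if total <= 0:
        warnings.warn("entropy of an all-zero count vector is undefined; returning NaN",
                      stacklevel=2)
        return float("nan")
    p = values[values > 0] / total
    return float(-(p * np.log2(p)).sum())


def _to_angles(hours: np.ndarray, period: float) -> np.ndarray:
    return 2.0 * np.pi * np.asarray(hours, dtype=float) / period


def circular_mean(hours: Iterable[float], period: float = 24.0) -> float:
    """Circular mean of clock values, returned in ``[0, period)``.

    NaNs are dropped; an empty (or all-NaN) input yields NaN.
    """
    h = np.asarray(list(hours), dtype=float)
    h = h[~np.isnan(h)]
    if h.size == 0:
        return float("nan")
    a = _to_angles(h, period)
    mean_angle = np.arctan2(np.sin(a).mean(), np.cos(a).mean())
    out = float((mean_angle * period / (2.0 * np.pi)) % period)
    return 0.0 if out >= period else out  # tiny negatives wrap to `period`


def circular_sd(hours: Iterable[float], period: float = 24.0) -> float:
    """Circular standard deviation ``sqrt(-2 ln R)`` expressed in hours.

    R is the mean resultant length.  A single observation gives 0; empty
    input gives NaN.  R very close to 0 (uniform spread) yields a large
    but finite value capped by the period.
    """
    h = np.asarray(list(hours), dtype=float)
    h = h[~np.isnan(h)]
    if h.size == 0:
        return float("nan")
    a = _to_angles(h, period)
    r = float(np.hypot(np.sin(a).mean(), np.cos(a).mean()))
    r = min(max(r, 1e-12), 1.0)
    sd_rad = np.sqrt(-2.0 * np.log(r))
    return float(min(sd_rad * period / (2.0 * np.pi), period))


def circular_median(hours: Iterable[float], period: float = 24.0) -> float:
    """Median of clock values taken after rotating the cut point opposite
    the circular mean, so that e.g. median of {23, 0, 1} is 0 not 8."""
    h = np.asarray(list(hours), dtype=float)
    h = h[~np.isnan(h)]
    if h.size == 0:
        return float("nan")
    center = circular_mean(h, period)
    shifted = (h - center + period / 2.0) % period
    med = float(np.median(shifted))
    return float((med + center - period / 2.0) % period)
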