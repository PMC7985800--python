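"""Two-period aggregation of features into sample-level vectors.

Each base feature ``f`` with period values ``(a, b)`` yields three
sample features: ``f.diff = b - a``, ``f.mean = (a + b) / 2`` and
``f.sd = |b - a| / sqrt(2)`` (the two-point sample SD, ddof=1).  NaN in
either period propagates to all three.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping

__all__ = ["aggregate_periods", "SQRT2"]

SQRT2 = math.sqrt(2.0)


def aggregate_periods(
    pf1: Mapping[str, float],
    pf2: Mapping[str, float],
) -> Dict[str, float]:
    """Combine the two period feature maps into one sample vector.

    Raises ``ValueError`` if the name sets differ.
    """
    if set(pf1) != set(pf2):
        missing = set(pf1) ^ set(pf2)
        raise ValueError(f"period feature name sets differ: {sorted(missing)[:5]} ...")
    out: Dict[str, float] = {}
    for name in pf1:
        a, b = float(pf1[name]), float(pf2[name])
        if math.isnan(a) or math.isnan(b):
            out[f"{name}.diff"] = float("nan")
            out[f"{name}.mean"] = float("nan")
            out[f"{name}.sd"] = float("nan")
        else:
            out[f"{name}.diff"] = b - a
            out[f"{name}.mean"] = (a + b) / 2.0
            out[f"{name}.sd"] = abs(b - a) / SQRT2
    return out
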