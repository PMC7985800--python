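"""Run configuration with paper-anchored defaults.

Every threshold that has a stated value defaults to it (7-day minimum
period, 3 effective days, 10 CV folds, eight app categories, eight
3-hour bins); everything else is an explicit, documented choice.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional, Union

import yaml
from pydantic import BaseModel, Field

__all__ = ["RunConfig", "load_config"]


class SynthParams(BaseModel):
    n_per_scenario: int = 4
    scenarios: List[str] = Field(default_factory=lambda: [
        "steady_remission", "steady_depressed", "swing_drastic",
        "swing_moderate", "null_effect",
    ])
    start: str = "2024-03-04T09:00:00+08:00"
    n_phq9: int = 3
    gap_days: float = 14.0
    jitter_days: float = 2.0
    effect_size: float = 1.5
    hr_noise_sd: float = 2.0


class SamplingParams(BaseModel):
    min_period_days: float = 7.0
    min_effective_days: int = 3
    min_worn_minutes: int = 240


class FeatureParams(BaseModel):
    bridge_min: float = 60.0
    min_sleep_min: float = 180.0
    cosinor_period_h: float = 24.0
    cosinor_min_points: int = 10


class SelectionParams(BaseModel):
    method: str = "l1"
    l1_strength: float = 1.0
    tree_threshold: Union[float, str] = "mean"
    selector_estimators: int = 100


class BenchParams(BaseModel):
    k: int = 10
    recall_kind: str = "positive"
    rf_estimators: int = 100
    combos: Optional[List[str]] = None
    tasks: Optional[List[str]] = None


class RunConfig(BaseModel):
    out_dir: str = "runs/latest"
    data_dir: Optional[str] = None  # when None, a cohort is synthesized
    seed: int = 0
    tz: str = "Asia/Shanghai"
    max_reject_rate: float = 0.05
    synth: SynthParams = Field(default_factory=SynthParams)
    sampling: SamplingParams = Field(default_factory=SamplingParams)
    features: FeatureParams = Field(default_factory=FeatureParams)
    selection: SelectionParams = Field(default_factory=SelectionParams)
    bench: BenchParams = Field(default_factory=BenchParams)

    def config_hash(self) -> str:
        """Hash of the analytical configuration (output location excluded)."""
        payload = self.model_dump()
        payload.pop("out_dir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def load_config(path: Optional[str | Path]) -> RunConfig:
    """Load a YAML config; missing path yields all defaults."""
    if path is None:
        return RunConfig()
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
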