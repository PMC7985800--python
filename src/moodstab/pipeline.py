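"""End-to-end orchestration: synth -> ingest -> samples -> features ->
bench, with provenance for full reproducibility."""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import sklearn

from . import __version__
from .bench import run_grid
from .config import RunConfig
from .features import build_manifest, extract_features
from .ingest import clean_screen_events, load_participant, load_phq9
from .sampling import DataSample, build_samples, samples_to_frame
from .synth import generate_cohort, iter_cohort

__all__ = ["run_all", "build_cohort_matrix", "participant_dirs"]


def participant_dirs(data_dir: Path) -> List[Path]:
    return sorted(p for p in Path(data_dir).iterdir() if p.is_dir())


def _feature_kwargs(cfg: RunConfig) -> dict:
    return dict(
        bridge_min=cfg.features.bridge_min,
        min_sleep_min=cfg.features.min_sleep_min,
        cosinor_period_h=cfg.features.cosinor_period_h,
        cosinor_min_points=cfg.features.cosinor_min_points,
    )


def build_cohort_matrix(
    cfg: RunConfig,
    scenario_weights: Optional[Dict[str, int]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort in memory and return (features, samples) tables.

    Participants are processed one at a time so raw minute-level frames
    are never all resident at once.
    """
    all_samples: List[DataSample] = []
    per_participant = []
    for profile, spec, streams, phq9 in iter_cohort(
        n_per_scenario=cfg.synth.n_per_scenario,
        seed=cfg.seed,
        scenarios=tuple(cfg.synth.scenarios),
        start=cfg.synth.start,
        n_phq9=cfg.synth.n_phq9,
        gap_days=cfg.synth.gap_days,
        jitter_days=cfg.synth.jitter_days,
        effect_size=cfg.synth.effect_size,
        hr_noise_sd=cfg.synth.hr_noise_sd,
        scenario_weights=scenario_weights,
    ):
        streams["screen"] = clean_screen_events(streams["screen"])
        samples = build_samples(
            profile.participant_id, streams, phq9,
            min_period_days=cfg.sampling.min_period_days,
            min_worn_minutes=cfg.sampling.min_worn_minutes,
        )
        all_samples.extend(samples)
        per_participant.append((streams, samples))
    features = extract_features(per_participant, **_feature_kwargs(cfg))
    samples_df = samples_to_frame(all_samples).set_index("sample_id")
    return features, samples_df


def _stage_samples(cfg: RunConfig, data_dir: Path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    all_samples: List[DataSample] = []
    per_participant = []
    for pdir in participant_dirs(data_dir):
        streams = load_participant(pdir, pdir.name, tz=cfg.tz,
                                   max_reject_rate=cfg.max_reject_rate)
        phq9 = load_phq9(streams)
        samples = build_samples(
            pdir.name, streams, phq9,
            min_period_days=cfg.sampling.min_period_days,
            min_worn_minutes=cfg.sampling.min_worn_minutes,
        )
        all_samples.extend(samples)
        per_participant.append((streams, samples))
    features = extract_features(per_participant, **_feature_kwargs(cfg))
    samples_df = samples_to_frame(all_samples).set_index("sample_id")
    return features, samples_df


def run_all(cfg: RunConfig) -> Path:
    """Run every stage and write artifacts + provenance under
    ``cfg.out_dir``.  Reruns with the same config and seed are
    byte-identical."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.data_dir is None:
        data_dir = out / "data"
        generate_cohort(
            cfg.synth.n_per_scenario, cfg.seed, data_dir,
            scenarios=tuple(cfg.synth.scenarios),
            start=cfg.synth.start,
            n_phq9=cfg.synth.n_phq9,
            gap_days=cfg.synth.gap_days,
            jitter_days=cfg.synth.jitter_days,
            effect_size=cfg.synth.effect_size,
            hr_noise_sd=cfg.synth.hr_noise_sd,
        )
    else:
        data_dir = Path(cfg.data_dir)

    features, samples_df = _stage_samples(cfg, data_dir)
    samples_df.to_csv(out / "samples.csv")
    features.to_csv(out / "features.csv")
    manifest = build_manifest([c for c in features.columns if c != "label"])
    with open(out / "feature_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    report = run_grid(
        features, samples_df.reset_index(),
        combos=cfg.bench.combos, tasks=cfg.bench.tasks,
        k=cfg.bench.k, seed=cfg.seed,
        min_effective_days=cfg.sampling.min_effective_days,
        selection=cfg.selection.method,
        l1_strength=cfg.selection.l1_strength,
        tree_threshold=cfg.selection.tree_threshold,
        recall_kind=cfg.bench.recall_kind,
        rf_estimators=cfg.bench.rf_estimators,
        selector_estimators=cfg.selection.selector_estimators,
    )
    report.to_json(out / "report.json")
    report.to_csv(out / "report.csv")
    report.to_markdown(out / "report.md")

    provenance = {
        "config": cfg.model_dump(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "moodstab": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
        "row_counts": {
            "samples": int(len(samples_df)),
            "features": int(len(features)),
            "feature_columns": int(features.shape[1] - 1),
            "report_rows": int(len(report.rows)),
        },
    }
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
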