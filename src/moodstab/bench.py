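"""Classifier benchmark: data-type combinations x classification tasks
x classifiers under stratified 10-fold cross-validation.

Each fold's pipeline is impute (median) -> standardize -> select ->
fit, all fit on the training fold only.  Reported recall is the
positive-class (Swing-side) recall by default; a macro option exists.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .select import FoldSelector, select_l1, select_tree

__all__ = [
    "TASKS",
    "COMBOS",
    "default_models",
    "make_pipeline",
    "run_cv",
    "run_grid",
    "permutation_null",
    "BenchReport",
]

#: classification tasks: negative (Steady-side) and positive (Swing-side) labels
TASKS: Dict[str, Dict[str, frozenset]] = {
    "steady_vs_swing": {
        "neg": frozenset({"steady_remission", "steady_depressed"}),
        "pos": frozenset({"swing_drastic", "swing_moderate"}),
    },
    "remission_vs_drastic": {
        "neg": frozenset({"steady_remission"}),
        "pos": frozenset({"swing_drastic"}),
    },
    "remission_vs_moderate": {
        "neg": frozenset({"steady_remission"}),
        "pos": frozenset({"swing_moderate"}),
    },
    "depressed_vs_drastic": {
        "neg": frozenset({"steady_depressed"}),
        "pos": frozenset({"swing_drastic"}),
    },
    "depressed_vs_moderate": {
        "neg": frozenset({"steady_depressed"}),
        "pos": frozenset({"swing_moderate"}),
    },
}

#: data-type combinations: which raw streams must pass the effective-day
#: rule, and which feature-name prefixes enter the matrix
COMBOS: Dict[str, Dict[str, Tuple[str, ...]]] = {
    "phone": {
        "kinds": ("call", "screen", "app"),
        "prefixes": ("call.", "screen.", "app."),
    },
    "sleep": {"kinds": ("wristband",), "prefixes": ("sleep.",)},
    "steps": {"kinds": ("wristband",), "prefixes": ("steps.",)},
    "heart_rate": {"kinds": ("wristband",), "prefixes": ("hr.",)},
    "all": {
        "kinds": ("call", "screen", "app", "wristband"),
        "prefixes": ("call.", "screen.", "app.", "sleep.", "steps.", "hr."),
    },
    "call_sleep_steps_hr": {
        "kinds": ("call", "wristband"),
        "prefixes": ("call.", "sleep.", "steps.", "hr."),
    },
}


def default_models(seed: int = 0, rf_estimators: int = 100) -> Dict[str, object]:
    """The six classifiers, with fixed widely-used default settings."""
    return {
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "knn": KNeighborsClassifier(),
        "logistic_regression": LogisticRegression(max_iter=2000, random_state=seed),
        "naive_bayes": GaussianNB(),
        "random_forest": RandomForestClassifier(
            n_estimators=rf_estimators, random_state=seed, n_jobs=1),
        "svm": SVC(random_state=seed),
    }


def make_pipeline(
    model,
    selection: str = "l1",
    l1_strength: float = 1.0,
    tree_threshold: float | str = "mean",
    seed: int = 0,
    selector_estimators: int = 100,
) -> Pipeline:
    return Pipeline([
        ("impute", SimpleImputer(strategy="median", keep_empty_features=True)),
        ("scale", StandardScaler()),
        ("select", FoldSelector(method=selection, strength=l1_strength,
                                threshold=tree_threshold, seed=seed,
                                n_estimators=selector_estimators)),
        ("model", model),
    ])


@dataclass
class FoldScores:
    accuracies: np.ndarray
    recalls: np.ndarray
    k_used: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1))

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.recalls))

    @property
    def sd_recall(self) -> float:
        return float(np.std(self.recalls, ddof=1))


def _fold_predictions(
    X: np.ndarray,
    y: np.ndarray,
    pipeline: Pipeline,
    k: int,
    seed: int,
    splits=None,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """(test index, predicted label) per fold; fits touch training folds only."""
    if splits is None:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
    out = []
    for train_idx, test_idx in splits:
        fitted = clone(pipeline).fit(X[train_idx], y[train_idx])
        out.append((test_idx, fitted.predict(X[test_idx])))
    return out


def run_cv(
    X,
    y,
    model,
    k: int = 10,
    seed: int = 0,
    recall_kind: str = "positive",
    **pipeline_kwargs,
) -> FoldScores:
    """Stratified k-fold CV of one classifier inside the full pipeline.

    ``y`` must be binary with 1 the positive (Swing-side) class.  If the
    smaller class has fewer than ``k`` members, k is reduced to that
    count with a warning — never silently.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("run_cv requires two classes in y")
    min_count = int(counts.min())
    if min_count < k:
        warnings.warn(
            f"smallest class has {min_count} members < k={k}; reducing folds "
            f"to {min_count}", stacklevel=2)
        k = min_count
    if k < 2:
        raise ValueError("need at least 2 members per class for CV")
    # a neighbor model cannot ask for more neighbors than a training fold holds
    n_train_min = len(y) - int(np.ceil(len(y) / k))
    if hasattr(model, "n_neighbors") and model.n_neighbors > n_train_min:
        model = clone(model).set_params(n_neighbors=max(1, n_train_min))
    pipeline = make_pipeline(model, seed=seed, **pipeline_kwargs)
    accs, recs = [], []
    for test_idx, pred in _fold_predictions(X, y, pipeline, k, seed):
        accs.append(accuracy_score(y[test_idx], pred))
        if recall_kind == "macro":
            recs.append(recall_score(y[test_idx], pred, average="macro",
                                     zero_division=0))
        else:
            recs.append(recall_score(y[test_idx], pred, pos_label=1,
                                     zero_division=0))
    return FoldScores(np.asarray(accs), np.asarray(recs), k_used=k)


def permutation_null(
    X,
    y,
    model,
    k: int = 10,
    n_perm: int = 200,
    seed: int = 0,
    **pipeline_kwargs,
) -> np.ndarray:
    """Null distribution of mean CV accuracy under label shuffling."""
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    out = np.empty(n_perm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_perm):
            y_perm = rng.permutation(y)
            out[i] = run_cv(X, y_perm, model, k=k, seed=seed,
                            **pipeline_kwargs).mean_accuracy
    return out


@dataclass
class BenchReport:
    """Per (combo, task) benchmark results, table-shaped."""

    rows: List[dict] = field(default_factory=list)
    config: Dict[str, object] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json(self, path: str | Path) -> None:
        def sanitize(obj):
            if isinstance(obj, dict):
                return {k: sanitize(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [sanitize(v) for v in obj]
            if isinstance(obj, float) and np.isnan(obj):
                return None
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        payload = sanitize({"config": self.config, "rows": self.rows})
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_markdown(self, path: str | Path) -> None:
        lines: List[str] = []
        df = self.to_frame()
        for combo in df["combo"].unique():
            sub = df[df["combo"] == combo]
            lines.append(f"## Classification results using {combo} features\n")
            lines.append("| Task (n neg / n pos) | Features selected | Best model "
                         "| Accuracy % (SD) | Recall % (SD) |")
            lines.append("|---|---|---|---|---|")
            for r in sub.to_dict("records"):
                lines.append(
                    f"| {r['task']} ({r['n_neg']}/{r['n_pos']}) "
                    f"| {r['n_features_selected']} | {r['best_model']} "
                    f"| {r['best_accuracy_mean']:.2f} ({r['best_accuracy_sd']:.2f}) "
                    f"| {r['best_recall_mean']:.2f} ({r['best_recall_sd']:.2f}) |"
                )
            lines.append("")
        Path(path).write_text("\n".join(lines), encoding="utf-8")


def _combo_columns(columns: Sequence[str], prefixes: Tuple[str, ...]) -> List[str]:
    return [c for c in columns if any(c.startswith(p) for p in prefixes)]


def run_grid(
    features: pd.DataFrame,
    samples: pd.DataFrame,
    combos: Optional[Sequence[str]] = None,
    tasks: Optional[Sequence[str]] = None,
    models: Optional[Mapping[str, object]] = None,
    k: int = 10,
    seed: int = 0,
    min_effective_days: int = 3,
    selection: str = "l1",
    l1_strength: float = 1.0,
    tree_threshold: float | str = "mean",
    recall_kind: str = "positive",
    rf_estimators: int = 100,
    selector_estimators: int = 100,
) -> BenchReport:
    """Run the full benchmark grid.

    ``features`` is indexed by sample_id with a ``label`` column;
    ``samples`` carries per-stream effective-day counts
    (``eff_<kind>_p1`` / ``eff_<kind>_p2``) indexed or keyed by
    sample_id.  A sample enters a combo only if every stream of that
    combo has >= ``min_effective_days`` effective days in both periods.
    """
    if "sample_id" in samples.columns:
        samples = samples.set_index("sample_id")
    combos = list(combos or COMBOS)
    tasks = list(tasks or TASKS)
    models = dict(models or default_models(seed=seed, rf_estimators=rf_estimators))
    pipeline_kwargs = dict(selection=selection, l1_strength=l1_strength,
                           tree_threshold=tree_threshold,
                           selector_estimators=selector_estimators)
    report = BenchReport(config={
        "k": k, "seed": seed, "selection": selection,
        "l1_strength": l1_strength, "tree_threshold": str(tree_threshold),
        "recall_kind": recall_kind, "min_effective_days": min_effective_days,
        "models": sorted(models), "rf_estimators": rf_estimators,
    })

    for combo_name in combos:
        combo = COMBOS[combo_name]
        usable_mask = pd.Series(True, index=samples.index)
        for kind in combo["kinds"]:
            usable_mask &= (samples[f"eff_{kind}_p1"] >= min_effective_days) & (
                samples[f"eff_{kind}_p2"] >= min_effective_days)
        usable_ids = samples.index[usable_mask]
        cols = _combo_columns(features.columns, combo["prefixes"])
        for task_name in tasks:
            task = TASKS[task_name]
            sub = features.loc[features.index.intersection(usable_ids)]
            sub = sub[sub["label"].isin(task["neg"] | task["pos"])]
            y = sub["label"].isin(task["pos"]).to_numpy(int)
            n_pos = int(y.sum())
            n_neg = int(len(y) - n_pos)
            row = {
                "combo": combo_name, "task": task_name,
                "n_neg": n_neg, "n_pos": n_pos,
            }
            if n_pos < 2 or n_neg < 2:
                row.update({
                    "n_features_selected": 0, "best_model": None,
                    "best_accuracy_mean": float("nan"),
                    "best_accuracy_sd": float("nan"),
                    "best_recall_mean": float("nan"),
                    "best_recall_sd": float("nan"),
                    "k_used": 0, "per_model": {},
                })
                report.rows.append(row)
                continue
            X = sub[cols].to_numpy(float)
            # selection size on the full task data, as a single reported n
            imputer = SimpleImputer(strategy="median", keep_empty_features=True)
            Xs = StandardScaler().fit_transform(imputer.fit_transform(X))
            if selection == "l1":
                sel = select_l1(Xs, y, strength=l1_strength, seed=seed)
            elif selection == "tree":
                sel = select_tree(Xs, y, threshold=tree_threshold, seed=seed,
                                  n_estimators=selector_estimators)
            else:
                sel = None
            row["n_features_selected"] = (
                len(sel.selected) if sel is not None else len(cols))
            per_model = {}
            for model_name in sorted(models):
                scores = run_cv(X, y, models[model_name], k=k, seed=seed,
                                recall_kind=recall_kind, **pipeline_kwargs)
                per_model[model_name] = {
                    "accuracy_mean": scores.mean_accuracy * 100.0,
                    "accuracy_sd": scores.sd_accuracy * 100.0,
                    "recall_mean": scores.mean_recall * 100.0,
                    "recall_sd": scores.sd_recall * 100.0,
                    "k_used": scores.k_used,
                }
            best = max(sorted(per_model), key=lambda m: per_model[m]["accuracy_mean"])
            row.update({
                "best_model": best,
                "best_accuracy_mean": per_model[best]["accuracy_mean"],
                "best_accuracy_sd": per_model[best]["accuracy_sd"],
                "best_recall_mean": per_model[best]["recall_mean"],
                "best_recall_sd": per_model[best]["recall_sd"],
                "k_used": per_model[best]["k_used"],
                "per_model": per_model,
            })
            report.rows.append(row)
    return report
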