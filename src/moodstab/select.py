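"""Feature selection: L1-sparsity and tree-importance schemes.

Both operate on an imputed, standardized matrix; inside the benchmark
they are re-fit on each training fold to avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

__all__ = ["SelectionResult", "select_l1", "select_tree", "FoldSelector"]


@dataclass
class SelectionResult:
    method: str
    selected: List[str]
    scores: Dict[str, float] = field(default_factory=dict)
    hyperparams: Dict[str, float] = field(default_factory=dict)
    seed: int = 0


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X),
                        columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])


def select_l1(X, y, strength: float = 1.0, seed: int = 0) -> SelectionResult:
    """Features with nonzero coefficients of an L1-penalized logistic
    regression (C = 1/strength).  Constant columns are never selected
    because their coefficient is exactly zero after standardization."""
    Xf = _as_frame(X)
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / strength, solver="liblinear",
                             random_state=seed, max_iter=1000)
    clf.fit(Xf.to_numpy(float), np.asarray(y))
    coef = np.abs(clf.coef_).ravel()
    mask = coef > 1e-10
    names = list(Xf.columns)
    return SelectionResult(
        method="l1",
        selected=[n for n, m in zip(names, mask) if m],
        scores={n: float(c) for n, c in zip(names, coef)},
        hyperparams={"strength": strength},
        seed=seed,
    )


def select_tree(
    X,
    y,
    threshold: float | str = "mean",
    seed: int = 0,
    n_estimators: int = 100,
) -> SelectionResult:
    """Features with ensemble importance >= ``threshold`` (default: mean
    importance), rank-ordered by decreasing importance."""
    Xf = _as_frame(X)
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                    n_jobs=1)
    forest.fit(Xf.to_numpy(float), np.asarray(y))
    imp = forest.feature_importances_
    thr = float(np.mean(imp)) if threshold == "mean" else float(threshold)
    names = list(Xf.columns)
    order = np.argsort(-imp, kind="stable")
    selected = [names[i] for i in order if imp[i] >= thr]
    return SelectionResult(
        method="tree",
        selected=selected,
        scores={n: float(v) for n, v in zip(names, imp)},
        hyperparams={"threshold": thr, "n_estimators": n_estimators},
        seed=seed,
    )


class FoldSelector(BaseEstimator, TransformerMixin):
    """sklearn-compatible wrapper so selection can sit inside a CV
    pipeline.  Guarantees at least one surviving feature (the top-scored
    one) so downstream estimators never see an empty matrix."""

    def __init__(self, method: str = "l1", strength: float = 1.0,
                 threshold: float | str = "mean", seed: int = 0,
                 n_estimators: int = 100):
        self.method = method
        self.strength = strength
        self.threshold = threshold
        self.seed = seed
        self.n_estimators = n_estimators

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if self.method == "l1":
            res = select_l1(X, y, strength=self.strength, seed=self.seed)
        elif self.method == "tree":
            res = select_tree(X, y, threshold=self.threshold, seed=self.seed,
                              n_estimators=self.n_estimators)
        elif self.method == "none":
            self.mask_ = np.ones(X.shape[1], dtype=bool)
            return self
        else:
            raise ValueError(f"unknown selection method {self.method!r}")
        cols = [int(n[1:]) for n in res.selected]  # _as_frame names are x<i>
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[cols] = True
        if not mask.any():
            scores = np.array([res.scores[f"x{i}"] for i in range(X.shape[1])])
            mask[int(np.argmax(scores))] = True
        self.mask_ = mask
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.mask_]
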