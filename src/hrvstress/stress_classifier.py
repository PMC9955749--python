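"""Repeated-split stress-classification harness.

Evaluation protocol: ten independent stratified 70/30 train/test splits
(seeds derived deterministically from one master seed).  Within each
training split a 10-fold cross-validated grid search selects the
hyperparameters by accuracy, the tuned model is refit on the full training
split, and the held-out 30% yields one confusion matrix.  Accuracy,
sensitivity (recall of the 'high'-stress class), specificity (recall of
'low') and F1 (positive class 'high') are aggregated over the ten repeats
as mean, SD and range.

Features are z-scored inside each training split (the scaler is fit on the
training data only and applied to the test data), because the
distance-based learners (KNN, RBF-SVM) are scale-sensitive.  Four families
are provided: RBF-kernel SVM, K-nearest neighbours (K = 1..10, Euclidean),
random forests (50/100/150 trees), and AdaBoost over depth-1 trees
(50/100/150 stumps, learning rate 0.1).  Everything not in a family's grid
is pinned explicitly so library defaults cannot drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "POSITIVE_CLASS",
    "ClassifierSpec",
    "SplitScore",
    "EvalReport",
    "DegenerateLabelsError",
    "default_specs",
    "build_design",
    "evaluate",
    "compare_scales",
    "report_summary_frame",
]

POSITIVE_CLASS = "high"
NEGATIVE_CLASS = "low"

#: Classifier input recommended by the surrogate analysis: the features that
#: remain valid stand-ins for their 5-min counterparts at every scale.
DEFAULT_INPUT_FEATURES = ("MeanNN", "SDNN", "NN20", "MeanHR")


class DegenerateLabelsError(ValueError):
    """Fewer than two classes present in the design matrix."""


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with its hyperparameter grid and pinned settings."""

    family: str
    grid: dict[str, list]
    fixed: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError(f"{self.family}: hyperparameter grid must be non-empty")

    def make_estimator(self, seed: int):
        if self.family == "svm_rbf":
            est = SVC(kernel="rbf", random_state=seed, **self.fixed)
        elif self.family == "knn":
            est = KNeighborsClassifier(metric="euclidean", **self.fixed)
        elif self.family == "random_forest":
            est = RandomForestClassifier(random_state=seed, **self.fixed)
        elif self.family == "adaboost":
            est = AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                learning_rate=0.1,
                random_state=seed,
                **self.fixed,
            )
        else:
            raise ValueError(f"unknown classifier family {self.family!r}")
        return est


def default_specs() -> dict[str, ClassifierSpec]:
    """The four classifier families with their search grids."""
    return {
        "svm_rbf": ClassifierSpec(
            "svm_rbf",
            grid={"model__C": [0.1, 1.0, 10.0, 100.0],
                  "model__gamma": ["scale", 0.01, 0.1, 1.0]},
        ),
        "knn": ClassifierSpec(
            "knn",
            grid={"model__n_neighbors": list(range(1, 11))},
        ),
        "random_forest": ClassifierSpec(
            "random_forest",
            grid={"model__n_estimators": [50, 100, 150]},
        ),
        "adaboost": ClassifierSpec(
            "adaboost",
            grid={"model__n_estimators": [50, 100, 150]},
        ),
    }


@dataclass(frozen=True)
class SplitScore:
    """Confusion matrix and derived metrics of one held-out test split."""

    tp: int
    tn: int
    fp: int
    fn: int
    best_params: dict

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else np.nan

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else np.nan

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else np.nan


METRICS = ("accuracy", "sensitivity", "specificity", "f1")


@dataclass(frozen=True)
class EvalReport:
    """Aggregate of the per-repeat test scores for one classifier family."""

    family: str
    scale: str
    splits: tuple[SplitScore, ...]
    positive_class: str = POSITIVE_CLASS

    @property
    def n_repeats(self) -> int:
        return len(self.splits)

    def scores(self, metric: str) -> np.ndarray:
        return np.array([getattr(s, metric) for s in self.splits], dtype=float)

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for metric in METRICS:
            v = self.scores(metric)
            out[metric] = {
                "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)),
                "min": float(np.min(v)), "max": float(np.max(v)),
            }
        return out

    def formatted(self, metric: str, percent: bool = True) -> str:
        """Table-style string 'mean ± sd (min–max)'."""
        s = self.summary()[metric]
        k = 100.0 if percent else 1.0
        return (f"{s['mean'] * k:.1f} ± {s['sd'] * k:.1f}"
                f"({s['min'] * k:.1f}–{s['max'] * k:.1f})")


def build_design(
    table: pd.DataFrame, scale: str,
    features: Sequence[str] = DEFAULT_INPUT_FEATURES,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Design matrix and labels for one scale.

    Rows with any missing requested feature are dropped; the count of
    dropped rows is returned for audit.
    """
    sub = table[table["scale"] == scale]
    X_full = sub[list(features)]
    keep = X_full.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    X = X_full[keep].to_numpy(dtype=float)
    y = sub.loc[keep, "label"].to_numpy(dtype=object)
    if np.unique(y).size < 2:
        raise DegenerateLabelsError(
            f"scale {scale}: need both classes, got {set(np.unique(y))}"
        )
    return X, y, n_dropped


def _derived_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-repeat seeds below 2^31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def evaluate(
    spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, seed: int,
    n_repeats: int = 10, test_size: float = 0.3, cv_folds: int = 10,
    scale: str = "",
) -> EvalReport:
    """Run the repeated-split protocol for one classifier family.

    Each repeat draws a stratified 70/30 split, grid-searches the family's
    hyperparameters by ``cv_folds``-fold stratified CV accuracy inside the
    training split (features z-scored within each CV training fold), refits
    on the whole training split, and scores the held-out test split.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DegenerateLabelsError("need both classes present")
    if counts.min() < cv_folds:
        cv_folds = max(2, int(counts.min()))

    splits: list[SplitScore] = []
    repeat_seeds = _derived_seeds(seed, n_repeats * 4)  # headroom for resplits
    si = 0
    while len(splits) < n_repeats:
        rs = repeat_seeds[si]
        si += 1
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_size, stratify=y, random_state=rs
        )
        if np.unique(y_tr).size < 2 or np.unique(y_te).size < 2:
            continue  # resplit with the next derived seed
        pipe = Pipeline([
            ("scaler", StandardScaler()),
            ("model", spec.make_estimator(rs)),
        ])
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rs)
        search = GridSearchCV(pipe, spec.grid, scoring="accuracy", cv=cv, n_jobs=1)
        search.fit(X_tr, y_tr)
        pred = search.best_estimator_.predict(X_te)
        tp = int(np.sum((pred == POSITIVE_CLASS) & (y_te == POSITIVE_CLASS)))
        tn = int(np.sum((pred != POSITIVE_CLASS) & (y_te != POSITIVE_CLASS)))
        fp = int(np.sum((pred == POSITIVE_CLASS) & (y_te != POSITIVE_CLASS)))
        fn = int(np.sum((pred != POSITIVE_CLASS) & (y_te == POSITIVE_CLASS)))
        splits.append(SplitScore(tp=tp, tn=tn, fp=fp, fn=fn,
                                 best_params=dict(search.best_params_)))
    return EvalReport(family=spec.family, scale=scale, splits=tuple(splits))


def compare_scales(
    table: pd.DataFrame,
    features: Sequence[str],
    specs: Sequence[ClassifierSpec],
    scales: Sequence[str],
    seed: int,
    **eval_kw,
) -> dict[tuple[str, str], EvalReport]:
    """EvalReport per (scale, family) cell, all derived from one seed."""
    reports: dict[tuple[str, str], EvalReport] = {}
    for scale in scales:
        X, y, _ = build_design(table, scale, features)
        for spec in specs:
            reports[(scale, spec.family)] = evaluate(
                spec, X, y, seed=seed, scale=scale, **eval_kw
            )
    return reports


def report_summary_frame(reports: dict[tuple[str, str], EvalReport]) -> pd.DataFrame:
    """Summary CSV shape: one row per (scale, family), formatted metric columns."""
    rows = []
    for (scale, family), rep in reports.items():
        row: dict[str, object] = {"scale": scale, "classifier": family}
        for metric in METRICS:
            s = rep.summary()[metric]
            row[metric] = (f"{s['mean'] * 100:.1f} ± {s['sd'] * 100:.1f}"
                           f"({s['min'] * 100:.1f}–{s['max'] * 100:.1f})")
            row[f"{metric}_mean"] = s["mean"]
            row[f"{metric}_sd"] = s["sd"]
        rows.append(row)
    return pd.DataFrame(rows)
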