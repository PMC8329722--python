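"""Cross-validated training, ROC/AUC evaluation and classifier comparison.

The central object is :class:`CvReport`: per-fold AUCs from a stratified
k-fold cross-validation, their arithmetic mean, and a pooled ROC curve built
from the out-of-fold scores.  Hyperparameter grids, when supplied, are
searched by nested cross-validation on the training folds only, so the
held-out fold never leaks into model selection.

Confusion-matrix metrics follow the usual definitions: sensitivity
TPR = TP/(TP+FN), specificity TNR = TN/(TN+FP), and fall-out
FPR = FP/(FP+TN) = 1 - TNR.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC


class UndefinedMetricError(ZeroDivisionError):
    """A confusion metric's denominator is zero."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Return (TPR, TNR, FPR) from raw confusion counts.

    FPR = 1 - TNR holds exactly.  Raises :class:`UndefinedMetricError`
    naming the metric whose denominator is zero.
    """
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("TPR undefined: no positive examples (TP+FN=0)")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("TNR/FPR undefined: no negative examples (TN+FP=0)")
    tpr = counts.tp / (counts.tp + counts.fn)
    tnr = counts.tn / (counts.tn + counts.fp)
    return tpr, tnr, 1.0 - tnr


def roc_and_auc(scores: Sequence[float],
                labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) and the area under the curve.

    Ties in the scores are handled by the trapezoidal rule, equivalently
    counting tied positive–negative pairs as 1/2 in the rank formulation.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC/AUC require both classes to be present")
    fpr, tpr, _ = roc_curve(y, scores)
    return np.column_stack([fpr, tpr]), float(roc_auc_score(y, scores))


# ---------------------------------------------------------------------------
# Classifier specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier with optional parameter overrides and search grid.

    ``grid="default"`` selects the documented default grid for the name;
    ``grid=None`` (default) disables the nested search.
    """

    name: str
    params: tuple = ()                      # ((key, value), ...) to stay hashable
    grid: str | tuple | None = None

    @property
    def params_dict(self) -> dict:
        return dict(self.params)


DEFAULT_PARAMS: dict[str, dict] = {
    "random_forest": {"n_estimators": 300},
    "svm": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    "naive_bayes": {},
    # small feed-forward network comparator; off the default spec list
    "dnn": {"hidden_layer_sizes": (32, 16), "max_iter": 600},
}

DEFAULT_GRIDS: dict[str, dict] = {
    "random_forest": {"n_estimators": [100, 300, 500],
                      "max_depth": [None, 10, 20],
                      "max_features": ["sqrt", "log2"]},
    "svm": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1]},
    "naive_bayes": {"var_smoothing": [1e-9, 1e-7, 1e-5]},
    "dnn": {"hidden_layer_sizes": [(32,), (32, 16)], "alpha": [1e-4, 1e-2]},
}

DEFAULT_SPECS = (ClassifierSpec("random_forest"), ClassifierSpec("svm"),
                 ClassifierSpec("naive_bayes"))


def make_estimator(spec: ClassifierSpec, seed: int):
    params = {**DEFAULT_PARAMS.get(spec.name, {}), **spec.params_dict}
    if spec.name == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if spec.name == "svm":
        return SVC(random_state=seed, **params)
    if spec.name == "naive_bayes":
        return GaussianNB(**params)
    if spec.name == "dnn":
        return MLPClassifier(random_state=seed, **params)
    raise ValueError(f"unknown classifier {spec.name!r}; "
                     f"available: {sorted(DEFAULT_PARAMS)}")


def _positive_scores(estimator, X) -> np.ndarray:
    """Continuous positive-class score: probability if available, else margin.

    Non-finite scores (e.g. Gaussian NB on zero-variance features) collapse
    to 0, i.e. an uninformative constant ranking.
    """
    if hasattr(estimator, "predict_proba"):
        s = estimator.predict_proba(X)[:, 1]
    else:
        s = estimator.decision_function(X)
    return np.nan_to_num(s, nan=0.0, posinf=0.0, neginf=0.0)


def _resolve_grid(spec: ClassifierSpec) -> dict | None:
    if spec.grid is None:
        return None
    if spec.grid == "default":
        return DEFAULT_GRIDS[spec.name]
    return dict(spec.grid)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    classifier_name: str
    hyperparameters: dict
    seed: int
    per_fold_auc: list[float]
    average_auc: float
    roc_points: np.ndarray                  # pooled out-of-fold (FPR, TPR)
    fold_assignment: np.ndarray = field(repr=False,
                                        default_factory=lambda: np.array([]))

    def to_json(self) -> str:
        return json.dumps({
            "classifier_name": self.classifier_name,
            "hyperparameters": self.hyperparameters,
            "seed": self.seed,
            "per_fold_auc": self.per_fold_auc,
            "average_auc": self.average_auc,
            "roc_points": np.asarray(self.roc_points).tolist(),
        }, indent=1, default=str)


def aggregate_fold_aucs(per_fold_auc: Sequence[float]) -> float:
    """The cross-validation summary statistic: the arithmetic mean of the
    per-fold AUCs."""
    return float(np.mean(np.asarray(per_fold_auc, dtype=float)))


def make_folds(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified fold partition, reusable across classifiers."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members, fewer "
                         f"than k={k} folds; use a smaller k")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validate(features, labels, spec: ClassifierSpec = ClassifierSpec("random_forest"),
                   k: int = 10, seed: int = 0,
                   folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
                   ) -> CvReport:
    """Stratified k-fold cross-validation with a pooled ROC curve.

    Each sample is tested exactly once; the per-fold AUC is computed on the
    held-out fold.  If the spec carries a grid, the best parameter
    combination is chosen per fold by an inner 3-fold search on the
    training portion only and refit before scoring.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if folds is None:
        folds = make_folds(y, k, seed)
    grid = _resolve_grid(spec)
    fold_assignment = np.full(len(y), -1, dtype=int)
    oof_scores = np.empty(len(y), dtype=float)
    per_fold_auc, per_fold_params = [], []
    for i, (train, test) in enumerate(folds):
        est = make_estimator(spec, seed)
        if grid:
            inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
            search = GridSearchCV(est, grid, scoring="roc_auc", cv=inner,
                                  n_jobs=1)
            search.fit(X[train], y[train])
            est = search.best_estimator_
            per_fold_params.append(search.best_params_)
        else:
            est = clone(est)
            est.fit(X[train], y[train])
            per_fold_params.append(est.get_params())
        s = _positive_scores(est, X[test])
        oof_scores[test] = s
        per_fold_auc.append(float(roc_auc_score(y[test], s)))
        fold_assignment[test] = i
    roc_points, _ = roc_and_auc(oof_scores, y)
    hyper = {"per_fold_best": per_fold_params} if grid else per_fold_params[0]
    return CvReport(classifier_name=spec.name, hyperparameters=hyper,
                    seed=seed, per_fold_auc=per_fold_auc,
                    average_auc=aggregate_fold_aucs(per_fold_auc),
                    roc_points=roc_points, fold_assignment=fold_assignment)


def compare_classifiers(features, labels,
                        specs: Sequence[ClassifierSpec] = DEFAULT_SPECS,
                        k: int = 10, seed: int = 0) -> list[CvReport]:
    """Paired comparison: every classifier sees the identical fold partition.

    Reports are returned sorted by average AUC, best first.
    """
    if len(specs) < 2:
        raise ValueError("need at least two classifier specs to compare")
    for s in specs:
        if s.name not in DEFAULT_PARAMS:
            raise ValueError(f"unknown classifier {s.name!r}; "
                             f"available: {sorted(DEFAULT_PARAMS)}")
    y = np.asarray(labels, dtype=int)
    folds = make_folds(y, k, seed)
    reports = [cross_validate(features, y, spec, k=k, seed=seed, folds=folds)
               for spec in specs]
    return sorted(reports, key=lambda r: (-r.average_auc, r.classifier_name))


def label_permutation_aucs(features, labels, spec: ClassifierSpec,
                           k: int, n_permutations: int, seed: int) -> list[float]:
    """Null distribution of the CV average AUC under label permutation."""
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=int)
    out = []
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        out.append(cross_validate(features, perm, spec, k=k, seed=seed).average_auc)
    return out


# ---------------------------------------------------------------------------
# Final model
# ---------------------------------------------------------------------------

class ColumnOrderError(ValueError):
    """Prediction-time features do not match the training column order."""


@dataclass
class FittedModel:
    """A trained classifier plus everything needed to audit its predictions:
    the feature column order, the spec and seed, and a fingerprint of the
    training set."""

    estimator: object
    feature_columns: tuple[str, ...]
    classifier_name: str
    params: dict
    seed: int
    training_fingerprint: str

    def predict_scores(self, features: pd.DataFrame) -> np.ndarray:
        """Positive-class scores; refuses silently-reordered columns."""
        cols = tuple(features.columns)
        if cols != self.feature_columns:
            raise ColumnOrderError(
                f"feature columns {list(cols)} do not match the training "
                f"order {list(self.feature_columns)}")
        return _positive_scores(self.estimator, np.asarray(features, dtype=float))

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "FittedModel":
        return joblib.load(path)


def train_final(features: pd.DataFrame, labels,
                spec: ClassifierSpec = ClassifierSpec("random_forest"),
                seed: int = 0) -> FittedModel:
    """Fit the production model on the full training set."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    X = np.asarray(features, dtype=float)
    est = make_estimator(spec, seed)
    est.fit(X, y)
    fp = hashlib.sha256(X.tobytes() + y.tobytes()).hexdigest()[:16]
    return FittedModel(estimator=est, feature_columns=tuple(features.columns),
                       classifier_name=spec.name,
                       params={**DEFAULT_PARAMS.get(spec.name, {}),
                               **spec.params_dict},
                       seed=seed, training_fingerprint=fp)
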