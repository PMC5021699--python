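"""Classifier ablation over the three-channel training file.

Four classifier families — decision tree, multilayer perceptron, naive
Bayes over the discrete features (the desk-scale reading of a Bayes
net on three ordinal variables), and a support vector machine — are
evaluated with stratified k-fold cross-validation on every non-empty
subset of the three features.  Metrics (precision, recall, F1, ROC
AUC) are computed on the pooled out-of-fold predictions with the
impaired class as the positive class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import (f1_score, precision_score, recall_score,
                             roc_curve)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import CategoricalNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .records import TrainingRecord

__all__ = ["FEATURES", "CLASSIFIERS", "CVResult", "MetricsReport",
           "build_training_file", "cross_validate", "ablation_study"]

FEATURES = ("polarity", "so_code", "tone_code")
CLASSIFIERS = ("decision_tree", "multilayer_perceptron", "bayes_net", "svm")
POSITIVE_LABEL = "case"

# feature value domains, used to encode categories for the naive Bayes
# family so unseen-in-fold levels are still representable
_DOMAIN_SIZE = {"polarity": 11, "so_code": 3, "tone_code": 3}
_OFFSET = {"polarity": 5, "so_code": 1, "tone_code": 1}


@dataclass(frozen=True)
class CVResult:
    """Pooled cross-validation metrics for one (features, classifier)."""

    feature_set: tuple[str, ...]
    classifier: str
    precision: float
    recall: float
    f1: float
    roc_auc: float
    roc_points: tuple[tuple[float, float], ...]
    folds: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "feature_set": list(self.feature_set),
            "classifier": self.classifier,
            "precision": round(float(self.precision), 10),
            "recall": round(float(self.recall), 10),
            "f1": round(float(self.f1), 10),
            "roc_auc": round(float(self.roc_auc), 10),
            "folds": self.folds,
            "seed": self.seed,
        }


@dataclass
class MetricsReport:
    """All ablation rows plus the pinned classifier configuration."""

    rows: list[CVResult]
    params: Mapping[str, Mapping] = field(default_factory=dict)

    def row(self, feature_set: Sequence[str], classifier: str) -> CVResult:
        key = tuple(feature_set)
        for r in self.rows:
            if r.feature_set == key and r.classifier == classifier:
                return r
        raise KeyError((key, classifier))

    def to_dict(self) -> dict:
        return {
            "params": {k: dict(v) for k, v in self.params.items()},
            "rows": [r.to_dict() for r in self.rows],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        """One table per feature set, rows = classifiers."""
        blocks = []
        for fs in sorted({r.feature_set for r in self.rows},
                         key=lambda t: (len(t), t)):
            lines = ["[" + "+".join(fs) + "]",
                     f"{'classifier':<24}{'precision':>10}{'recall':>10}"
                     f"{'f1':>10}{'roc_auc':>10}"]
            for r in self.rows:
                if r.feature_set == fs:
                    lines.append(f"{r.classifier:<24}{r.precision:>10.3f}"
                                 f"{r.recall:>10.3f}{r.f1:>10.3f}"
                                 f"{r.roc_auc:>10.3f}")
            blocks.append("\n".join(lines))
        return "\n\n".join(blocks)


def build_training_file(scored: pd.DataFrame) -> list[TrainingRecord]:
    """Join the three scored channels into training records.

    ``scored`` needs columns ``phrase_id``, ``class``, ``polarity``,
    ``so_code`` and ``tone_code``; a missing value raises an error that
    names the offending phrase.  Row order is preserved.
    """
    required = ["phrase_id", "class", "polarity", "so_code", "tone_code"]
    missing_cols = [c for c in required if c not in scored.columns]
    if missing_cols:
        raise ValueError(f"scored table is missing columns {missing_cols}")
    records = []
    for _, row in scored.iterrows():
        for col in ("class", "polarity", "so_code", "tone_code"):
            if pd.isna(row[col]):
                raise ValueError(
                    f"phrase {row['phrase_id']!r}: missing channel "
                    f"value {col!r}")
        records.append(TrainingRecord(str(row["class"]), int(row["polarity"]),
                                      int(row["so_code"]),
                                      int(row["tone_code"])))
    return records


def _classifier_params(seed: int) -> dict[str, dict]:
    return {
        "decision_tree": {"class": "DecisionTreeClassifier",
                          "random_state": seed},
        "multilayer_perceptron": {"class": "MLPClassifier",
                                  "random_state": seed, "max_iter": 200},
        "bayes_net": {"class": "CategoricalNB",
                      "note": "naive Bayes over the discrete features"},
        "svm": {"class": "SVC", "random_state": seed,
                "score": "min-max scaled decision_function"},
    }


def _make_classifier(name: str, feature_set: Sequence[str], seed: int):
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "multilayer_perceptron":
        return MLPClassifier(random_state=seed)
    if name == "bayes_net":
        min_cats = [_DOMAIN_SIZE[f] for f in feature_set]
        return CategoricalNB(min_categories=np.array(min_cats))
    if name == "svm":
        return SVC(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; "
                     f"expected one of {CLASSIFIERS}")


def _feature_matrix(records: Sequence[TrainingRecord],
                    feature_set: Sequence[str], encode: bool) -> np.ndarray:
    getters = {"polarity": lambda r: r.polarity,
               "so_code": lambda r: r.so_code,
               "tone_code": lambda r: r.tone_code}
    X = np.array([[getters[f](r) for f in feature_set] for r in records],
                 dtype=float)
    if encode:  # shift to 0-based categories for CategoricalNB
        X = X + np.array([_OFFSET[f] for f in feature_set])
    return X


def _positive_scores(clf, X: np.ndarray, positive_label: str) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        proba = clf.predict_proba(X)
        idx = int(np.where(clf.classes_ == positive_label)[0][0])
        return proba[:, idx]
    scores = clf.decision_function(X)
    # decision_function is oriented toward classes_[1]
    if clf.classes_[1] != positive_label:
        scores = -scores
    return scores


def cross_validate(
    records: Sequence[TrainingRecord],
    feature_set: Sequence[str],
    classifier: str,
    folds: int = 10,
    seed: int = 0,
    positive_label: str = POSITIVE_LABEL,
) -> CVResult:
    """Stratified k-fold CV of one classifier on one feature subset.

    Predictions and scores are pooled across the held-out folds before
    computing precision, recall, F1 and the ROC curve, with
    ``positive_label`` as the positive class.  Score-based ROC uses
    class-membership probabilities where the family provides them and
    min-max scaled decision values otherwise.
    """
    feature_set = tuple(feature_set)
    if not feature_set or any(f not in FEATURES for f in feature_set):
        raise ValueError(f"feature_set must be a non-empty subset of "
                         f"{FEATURES}, got {feature_set}")
    y = np.array([r.class_label for r in records])
    classes = set(y.tolist())
    if len(classes) < 2:
        raise ValueError("cross-validation needs both classes present, "
                         f"got only {sorted(classes)}")
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} absent from "
                         f"data (classes {sorted(classes)})")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < folds:
        raise ValueError(f"need at least {folds} records per class for "
                         f"{folds}-fold stratified CV, got {counts}")
    X = _feature_matrix(records, feature_set, encode=classifier == "bayes_net")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    y_score = np.empty(len(y), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train_idx, test_idx in skf.split(X, y):
            clf = _make_classifier(classifier, feature_set, seed)
            clf.fit(X[train_idx], y[train_idx])
            y_pred[test_idx] = clf.predict(X[test_idx])
            y_score[test_idx] = _positive_scores(clf, X[test_idx],
                                                 positive_label)
    if y_score.max() > y_score.min():
        y_score = (y_score - y_score.min()) / (y_score.max() - y_score.min())
    precision = precision_score(y, y_pred, pos_label=positive_label,
                                zero_division=0)
    recall = recall_score(y, y_pred, pos_label=positive_label,
                          zero_division=0)
    f1 = f1_score(y, y_pred, pos_label=positive_label, zero_division=0)
    fpr, tpr, _ = roc_curve(y, y_score, pos_label=positive_label)
    auc = float(np.trapezoid(tpr, fpr))
    points = tuple(zip(fpr.tolist(), tpr.tolist()))
    return CVResult(feature_set, classifier, float(precision), float(recall),
                    float(f1), auc, points, folds, seed)


def ablation_study(
    records: Sequence[TrainingRecord],
    folds: int = 10,
    seed: int = 0,
    positive_label: str = POSITIVE_LABEL,
) -> MetricsReport:
    """Cross-validate all 7 feature subsets x 4 classifier families."""
    subsets = [fs for k in (1, 2, 3) for fs in combinations(FEATURES, k)]
    rows = [
        cross_validate(records, fs, clf, folds=folds, seed=seed,
                       positive_label=positive_label)
        for fs in subsets
        for clf in CLASSIFIERS
    ]
    return MetricsReport(rows, params=_classifier_params(seed))
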