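"""Seeded k-fold cross-validation harness and a threshold-picking classifier.

The marker-score classifier the study pipeline evaluates is treated as an
injectable scorer: anything with ``fit(X, y)`` and a score method
(``predict_proba`` or ``decision_function``) mapping subjects to a risk score
in [0, 1]. The harness randomises subjects into k near-equal folds (k = 3 by
default, labelled A, B, C), trains on k-1 folds, scores the held-out fold,
and pools the out-of-fold scores into one ROC from which an operating
threshold is chosen (Youden's J, or the highest threshold still meeting a
target sensitivity).

:class:`ScoreThresholdClassifier` wraps the same procedure as a
scikit-learn estimator so it composes with pipelines and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from string import ascii_uppercase
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .diagnostics import OperatingPoint, roc_auc

__all__ = [
    "FoldAssignment",
    "CVResult",
    "PassthroughScorer",
    "ScoreThresholdClassifier",
    "assign_folds",
    "cross_validate",
    "choose_threshold",
    "select_threshold",
]

FEATURE_SETS = {"voc": ["voc_score"], "voc+fit": ["voc_score", "fit_ug_g"]}


def _fold_label(i: int, k: int) -> str:
    return ascii_uppercase[i] if k <= 26 else str(i + 1)


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of subject ids into k near-equal folds."""

    mapping: dict[str, str]
    k: int
    seed: int

    def fold_ids(self, label: str) -> list[str]:
        return [sid for sid, lab in self.mapping.items() if lab == label]

    @property
    def labels(self) -> list[str]:
        return [_fold_label(i, self.k) for i in range(self.k)]


@dataclass(frozen=True)
class CVResult:
    """Pooled out-of-fold scores and the ROC they induce."""

    scores: pd.Series  # subject_id -> out-of-fold score
    folds: FoldAssignment
    y_true: pd.Series  # subject_id -> disease status
    fold_models: dict[str, object]
    chosen_threshold: float | None = None

    def operating_points(self) -> list[OperatingPoint]:
        return _points_from_scores(self.scores.to_numpy(), self.y_true.to_numpy())

    def auc(self) -> float:
        return roc_auc(self.operating_points(), anchored=True)


def assign_folds(subject_ids: Sequence[str], k: int, seed: int) -> FoldAssignment:
    """Seeded uniform partition into k folds whose sizes differ by at most 1."""
    ids = list(subject_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"need at least k={k} subjects; got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    mapping: dict[str, str] = {}
    for i, chunk in enumerate(np.array_split(order, k)):
        for j in chunk:
            mapping[ids[j]] = _fold_label(i, k)
    return FoldAssignment(mapping=mapping, k=k, seed=seed)


def _stratified_folds(
    subject_ids: Sequence[str], y: np.ndarray, k: int, seed: int
) -> FoldAssignment:
    # per-class shuffled round-robin: every fold sees both classes when possible
    ids = np.asarray(list(subject_ids))
    rng = np.random.default_rng(seed)
    mapping: dict[str, str] = {}
    slot = 0
    for cls in (1, 0):
        cls_ids = ids[y == cls]
        for sid in cls_ids[rng.permutation(len(cls_ids))]:
            mapping[str(sid)] = _fold_label(slot % k, k)
            slot += 1
    return FoldAssignment(mapping=mapping, k=k, seed=seed)


def _score_with(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))[:, 1]
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    raise TypeError("learner must expose predict_proba or decision_function")


def cross_validate(
    records: pd.DataFrame,
    features: Sequence[str] | str = "voc",
    k: int = 3,
    seed: int = 0,
    learner=None,
    *,
    stratified: bool = False,
) -> CVResult:
    """Train on k-1 folds, score the held-out fold, for every fold.

    Every subject is scored exactly once, by a model that never saw it. If a
    training split turns out single-class, folds are reassigned with the
    stratified scheme (same seed) and a warning is issued.
    """
    cols = FEATURE_SETS.get(features, features) if isinstance(features, str) else list(features)
    if isinstance(cols, str):
        raise ValueError(f"unknown feature set {features!r}; use {sorted(FEATURE_SETS)}")
    learner = learner if learner is not None else LogisticRegression()
    ids = records["subject_id"].astype(str).to_numpy()
    X = records[list(cols)].to_numpy(dtype=float)
    y = records["diseased"].to_numpy(dtype=int)

    folds = assign_folds(ids, k=k, seed=seed)
    labels = np.array([folds.mapping[sid] for sid in ids])
    for lab in folds.labels:
        if len(np.unique(y[labels != lab])) < 2:
            warnings.warn(
                "single-class training fold under simple randomisation; "
                "reassigning folds with stratification"
            )
            folds = _stratified_folds(ids, y, k=k, seed=seed)
            labels = np.array([folds.mapping[sid] for sid in ids])
            break

    scores = np.full(len(ids), np.nan)
    fold_models: dict[str, object] = {}
    for lab in folds.labels:
        test_mask = labels == lab
        train_mask = ~test_mask
        model = clone(learner) if isinstance(learner, BaseEstimator) else learner
        model.fit(X[train_mask], y[train_mask])
        scores[test_mask] = _score_with(model, X[test_mask])
        fold_models[lab] = model

    return CVResult(
        scores=pd.Series(scores, index=ids, name="oof_score"),
        folds=folds,
        y_true=pd.Series(y, index=ids, name="diseased"),
        fold_models=fold_models,
    )


class PassthroughScorer(BaseEstimator):
    """Identity learner: the score IS the (single) input feature. No training."""

    def __init__(self, column: int = 0):
        self.column = column

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float)[:, self.column]


def _points_from_scores(scores: np.ndarray, y: np.ndarray) -> list[OperatingPoint]:
    n_dis = int((y == 1).sum())
    n_hea = int((y == 0).sum())
    if n_dis == 0 or n_hea == 0:
        raise ValueError("ROC needs both classes present")
    points = []
    for t in np.unique(scores):
        positive = scores >= t
        points.append(
            OperatingPoint(
                threshold=float(t),
                tpr=float((positive & (y == 1)).sum() / n_dis),
                fpr=float((positive & (y == 0)).sum() / n_hea),
            )
        )
    return points


def select_threshold(
    points: Sequence[OperatingPoint],
    policy: Literal["youden", "target_sensitivity"] = "youden",
    target_sensitivity: float | None = None,
) -> float:
    """Pick an operating threshold from ROC vertices.

    youden: maximise J = tpr - fpr (ties: higher specificity, then higher
    threshold). target_sensitivity: among thresholds whose sensitivity still
    meets the target, take the most specific (ties toward the higher
    threshold); raises if the target is unattainable, naming the maximum.
    """
    if len(points) == 0:
        raise ValueError("no operating points to choose from")
    if policy == "youden":
        best = max(points, key=lambda p: (p.tpr - p.fpr, -p.fpr, p.threshold))
        return best.threshold
    if policy == "target_sensitivity":
        if target_sensitivity is None:
            raise ValueError("target_sensitivity policy needs a target")
        feasible = [p for p in points if p.tpr >= target_sensitivity]
        if not feasible:
            best_attainable = max(p.tpr for p in points)
            raise ValueError(
                f"target sensitivity {target_sensitivity} unattainable; "
                f"maximum attainable is {best_attainable:.4f}"
            )
        best = max(feasible, key=lambda p: (-p.fpr, p.threshold))
        return best.threshold
    raise ValueError(f"unknown policy {policy!r}")


def choose_threshold(
    result: CVResult | Sequence[OperatingPoint],
    policy: Literal["youden", "target_sensitivity"] = "youden",
    target_sensitivity: float | None = None,
) -> float:
    """As :func:`select_threshold`, accepting a CVResult's pooled scores."""
    points = result.operating_points() if isinstance(result, CVResult) else list(result)
    return select_threshold(points, policy=policy, target_sensitivity=target_sensitivity)


class ScoreThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier = injectable scorer + CV-chosen threshold.

    fit() runs the seeded k-fold harness on the training data, picks the
    operating threshold from the pooled out-of-fold ROC, then refits the
    scorer on all of it. predict() is ``score >= threshold_``.

    Parameters
    ----------
    learner : estimator with fit + predict_proba/decision_function
        Default: logistic regression.
    k : folds for the internal CV used only to pick the threshold.
    policy : "youden" or "target_sensitivity".
    target_sensitivity : required when policy="target_sensitivity".
    seed : fold-assignment seed.
    """

    def __init__(
        self,
        learner=None,
        k: int = 3,
        policy: str = "youden",
        target_sensitivity: float | None = None,
        seed: int = 0,
    ):
        self.learner = learner
        self.k = k
        self.policy = policy
        self.target_sensitivity = target_sensitivity
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary 0/1")
        self.classes_ = np.array([0, 1])
        records = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        records["subject_id"] = [str(i) for i in range(len(records))]
        records["diseased"] = y
        base = self.learner if self.learner is not None else LogisticRegression()
        cv_result = cross_validate(
            records,
            features=[f"f{i}" for i in range(X.shape[1])],
            k=self.k,
            seed=self.seed,
            learner=base,
        )
        self.threshold_ = choose_threshold(
            cv_result, policy=self.policy, target_sensitivity=self.target_sensitivity
        )
        self.cv_result_ = cv_result
        self.learner_ = clone(base) if isinstance(base, BaseEstimator) else base
        self.learner_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "learner_")
        return _score_with(self.learner_, np.asarray(X, dtype=float))

    def predict(self, X):
        return (self.decision_function(X) >= self.threshold_).astype(int)
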