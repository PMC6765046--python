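"""Random-forest pair classifier: training, evaluation and control runs.

The classifier consumes the per-pair z-feature rows and predicts the
probability that a pair is functional. Training and testing sets are
class-balanced and mutually exclusive. Control experiments re-draw splits
(resampling) or permute class labels while preserving class counts
(label shuffling); shuffling destroys the feature-label relationship, so a
sound pipeline scores at chance (AUROC ~ 0.5) under it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    average_precision_score,
    matthews_corrcoef,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .exceptions import DataError, EvaluationError

DEFAULT_TREE_COUNTS = (10, 20, 50, 100, 200, 500, 1000, 2000, 5000)


@dataclass
class DatasetSplit:
    """Balanced, mutually exclusive train/test feature tables."""

    X_train: pd.DataFrame
    y_train: np.ndarray
    X_test: pd.DataFrame
    y_test: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.X_train.index) & set(self.X_test.index)
        if overlap:
            raise DataError(f"train/test overlap on {len(overlap)} pairs")


def sample_balanced_split(
    X: pd.DataFrame,
    y: Sequence[int],
    n_train_per_class: int,
    n_test_per_class: int,
    seed: int = 0,
) -> DatasetSplit:
    """Draw disjoint balanced train/test sets from a labeled feature table."""
    y = np.asarray(y, dtype=int)
    if len(y) != len(X):
        raise DataError("X and y lengths differ")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    need = n_train_per_class + n_test_per_class
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        if len(members) < need:
            raise DataError(
                f"class {cls}: need {need} pairs, only {len(members)} available"
            )
        chosen = rng.permutation(members)[:need]
        train_idx.extend(chosen[:n_train_per_class])
        test_idx.extend(chosen[n_train_per_class:])
    train_idx = sorted(train_idx)
    test_idx = sorted(test_idx)
    return DatasetSplit(
        X_train=X.iloc[train_idx],
        y_train=y[train_idx],
        X_test=X.iloc[test_idx],
        y_test=y[test_idx],
        seed=seed,
    )


@dataclass
class PairClassifier:
    """A trained forest plus the feature order it expects."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    seed: int
    n_trees: int

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the functional class for each row."""
        X = X[list(self.feature_names)]
        proba = self.forest.predict_proba(X.values)
        positive_col = list(self.forest.classes_).index(1)
        return proba[:, positive_col]

    def feature_importances(self) -> pd.Series:
        return pd.Series(
            self.forest.feature_importances_, index=list(self.feature_names)
        )

    def manifest(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "seed": self.seed,
            "feature_names": list(self.feature_names),
            "hyperparameters": {
                k: v
                for k, v in self.forest.get_params().items()
                if k in ("n_estimators", "max_depth", "max_features", "criterion")
            },
        }


def train_forest(
    split: DatasetSplit, n_trees: int = 100, seed: int = 0,
    feature_subset: Sequence[str] | None = None,
) -> PairClassifier:
    """Fit a seeded random forest on the training half of a split.

    ``feature_subset`` restricts training to the named columns (used by the
    leave-one-tissue-out ablations); default is every column.
    """
    names = tuple(feature_subset) if feature_subset else tuple(split.X_train.columns)
    X = split.X_train[list(names)]
    if not np.isfinite(X.values).all():
        raise DataError("training features contain NaN or Inf")
    if len(np.unique(split.y_train)) < 2:
        raise DataError("training labels contain a single class")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(X.values, split.y_train)
    return PairClassifier(forest, names, seed, n_trees)


@dataclass
class EvaluationReport:
    accuracy: float
    auroc: float
    auprc: float
    precision: float
    recall: float
    f1: float
    mcc: float
    curves: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "auroc": self.auroc,
            "auprc": self.auprc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
        }


def evaluate(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> EvaluationReport:
    """Standard binary metrics at the given probability threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise EvaluationError("scores and labels differ in length")
    if len(np.unique(labels)) < 2:
        raise EvaluationError("evaluation requires both classes present")
    predicted = (scores >= threshold).astype(int)
    tp = int(((predicted == 1) & (labels == 1)).sum())
    tn = int(((predicted == 0) & (labels == 0)).sum())
    fp = int(((predicted == 1) & (labels == 0)).sum())
    fn = int(((predicted == 0) & (labels == 1)).sum())
    accuracy = (tp + tn) / len(labels)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    mcc = float(matthews_corrcoef(labels, predicted))
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    prec_curve, rec_curve, pr_thr = precision_recall_curve(labels, scores)
    return EvaluationReport(
        accuracy=float(accuracy),
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        mcc=mcc,
        curves={
            "fpr": fpr,
            "tpr": tpr,
            "roc_thresholds": roc_thr,
            "pr_precision": prec_curve,
            "pr_recall": rec_curve,
            "pr_thresholds": pr_thr,
        },
    )


def stratified_kfold(
    X: pd.DataFrame,
    y: Sequence[int],
    k: int = 10,
    n_trees: int = 100,
    seed: int = 0,
) -> list[EvaluationReport]:
    """Stratified k-fold cross-validation preserving class frequencies."""
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if k > counts.min():
        raise DataError(f"k = {k} exceeds the smaller class count {counts.min()}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for train_ids, test_ids in splitter.split(X.values, y):
        split = DatasetSplit(
            X_train=X.iloc[train_ids],
            y_train=y[train_ids],
            X_test=X.iloc[test_ids],
            y_test=y[test_ids],
            seed=seed,
        )
        clf = train_forest(split, n_trees=n_trees, seed=seed)
        reports.append(evaluate(clf.predict_proba(split.X_test), split.y_test))
    return reports


def randomization_suite(
    X: pd.DataFrame,
    y: Sequence[int],
    n_reps: int,
    mode: str,
    n_train_per_class: int,
    n_test_per_class: int,
    n_trees: int = 100,
    seed: int = 0,
) -> list[EvaluationReport]:
    """Repeated control runs: 'resample' re-draws splits; 'shuffle_labels'
    permutes labels (class counts preserved) before splitting."""
    if mode not in ("resample", "shuffle_labels"):
        raise DataError(f"unknown randomization mode: {mode!r}")
    if n_reps < 1:
        raise DataError("n_reps must be >= 1")
    y = np.asarray(y, dtype=int)
    reports = []
    for rep in range(n_reps):
        rep_seed = (seed + 7919 * rep) % (2**31 - 1)
        y_rep = y
        if mode == "shuffle_labels":
            rng = np.random.default_rng(rep_seed)
            y_rep = rng.permutation(y)
        split = sample_balanced_split(
            X, y_rep, n_train_per_class, n_test_per_class, seed=rep_seed
        )
        clf = train_forest(split, n_trees=n_trees, seed=rep_seed)
        reports.append(evaluate(clf.predict_proba(split.X_test), split.y_test))
    return reports


def tree_sweep(
    split: DatasetSplit,
    tree_counts: Iterable[int] = DEFAULT_TREE_COUNTS,
    seed: int = 0,
) -> pd.DataFrame:
    """Metric-vs-tree-count table over the default 9-count sweep."""
    rows = []
    for n_trees in tree_counts:
        clf = train_forest(split, n_trees=n_trees, seed=seed)
        report = evaluate(clf.predict_proba(split.X_test), split.y_test)
        rows.append({"n_trees": n_trees, **report.as_dict()})
    return pd.DataFrame(rows).set_index("n_trees")
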