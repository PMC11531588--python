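"""Grouped stratified cross-validation and classification metrics.

Buckets are the grouping unit: every local voxel cut from one bucket shares
that bucket's role (train / validation / test) within a fold, so no fold is
evaluated on voxels overlapping its training material. The 5-fold plan
assigns whole buckets — one fold's buckets as test, the next fold's as
validation, the remaining three as training — which realizes the 60/20/20
split at fold granularity.

Headline metrics (accuracy, F1, ROC-AUC, and their macro-averaged
multiclass variants) are computed on the pooled test predictions
concatenated across folds; per-fold and per-bucket breakdowns are also
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score as _sk_f1,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedGroupKFold


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. single-class ROC-AUC)."""


# --------------------------------------------------------------- fold plan
@dataclass
class FoldPlan:
    """Assignment of buckets (groups) to folds and roles.

    ``bucket_fold[b]`` is the fold in which bucket ``b`` is in the test
    role; in fold ``f`` the validation buckets are those of fold
    ``(f + 1) % n_folds`` and the rest train.
    """

    n_folds: int
    bucket_fold: dict[str, int]
    groups: np.ndarray  # bucket_id per sample
    strata: np.ndarray  # label per sample

    def role_of_bucket(self, bucket: str, fold: int) -> str:
        bf = self.bucket_fold[bucket]
        if bf == fold:
            return "test"
        if bf == (fold + 1) % self.n_folds:
            return "val"
        return "train"

    def roles(self, fold: int) -> np.ndarray:
        """Per-sample role array for one fold."""
        return np.array(
            [self.role_of_bucket(b, fold) for b in self.groups], dtype=object
        )

    def mask(self, fold: int, role: str) -> np.ndarray:
        return self.roles(fold) == role

    def validate(self) -> None:
        """Assert group integrity and the test-partition property."""
        n = len(self.groups)
        test_count = np.zeros(n, dtype=int)
        for fold in range(self.n_folds):
            roles = self.roles(fold)
            for role in ("train", "val", "test"):
                buckets = set(self.groups[roles == role])
                for other in ("train", "val", "test"):
                    if other != role:
                        overlap = buckets & set(self.groups[roles == other])
                        if overlap:
                            raise AssertionError(
                                f"buckets {overlap} span roles {role}/{other} "
                                f"in fold {fold}"
                            )
            test_count += (roles == "test").astype(int)
        if not np.all(test_count == 1):
            raise AssertionError("test sets do not partition the samples")


def make_fold_plan(
    samples: pd.DataFrame,
    n_folds: int = 5,
    seed: int = 0,
    group_col: str = "bucket_id",
    label_col: str = "label",
) -> FoldPlan:
    """Stratified group k-fold over a sample table.

    Groups are buckets; strata are the sample labels. Deterministic for a
    fixed seed.
    """
    groups = samples[group_col].to_numpy()
    labels = samples[label_col].to_numpy()
    n_buckets = len(pd.unique(groups))
    if n_buckets < n_folds:
        raise ValueError(
            f"need at least {n_folds} distinct buckets for {n_folds}-fold "
            f"cross-validation; got {n_buckets}"
        )
    sgkf = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    bucket_fold: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(
        sgkf.split(np.zeros(len(labels)), labels, groups)
    ):
        for b in pd.unique(groups[test_idx]):
            bucket_fold[b] = fold
    plan = FoldPlan(
        n_folds=n_folds, bucket_fold=bucket_fold, groups=groups, strata=labels
    )
    plan.validate()
    return plan


# ----------------------------------------------------------------- metrics
def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 (with a warning) at p=r=0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision == 0 and recall == 0:
        warnings.warn("F1 undefined at precision = recall = 0; returning 0")
        return 0.0
    return 2 * precision * recall / (precision + recall)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Binary ROC-AUC (midrank tie handling, equals the normalized
    Mann-Whitney U statistic)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError(
            "ROC-AUC undefined: only one class present in labels"
        )
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def macro_roc_auc(probs: np.ndarray, labels: np.ndarray, n_classes: int) -> float:
    """One-vs-rest ROC-AUC averaged over classes."""
    labels = np.asarray(labels)
    aucs = []
    for cls in range(n_classes):
        binary = (labels == cls).astype(int)
        if len(np.unique(binary)) < 2:
            raise UndefinedMetricError(
                f"macro ROC-AUC undefined: class {cls} absent from labels"
            )
        aucs.append(roc_auc(probs[:, cls], binary))
    return float(np.mean(aucs))


@dataclass
class MetricReport:
    """Classification metrics for one (or the pooled) test set."""

    accuracy: float
    f1: float
    roc_auc: float
    confusion: np.ndarray
    per_bucket_accuracy: dict[str, float] = field(default_factory=dict)
    n_test: int = 0
    task: str = "presence"

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
            "confusion": self.confusion.tolist(),
            "per_bucket_accuracy": self.per_bucket_accuracy,
            "n_test": self.n_test,
        }


def evaluate_predictions(
    y_true: np.ndarray,
    probs: np.ndarray,
    bucket_ids: np.ndarray,
    task: str = "presence",
) -> MetricReport:
    """Metric report from integer labels and per-class probabilities.

    Binary task: F1 and ROC-AUC of the positive (presence) class. Count
    task: macro-averaged F1 and one-vs-rest macro ROC-AUC.
    """
    y_true = np.asarray(y_true, dtype=int)
    if len(y_true) == 0:
        raise ValueError("empty test set")
    probs = np.asarray(probs, dtype=float)
    y_pred = probs.argmax(axis=1)
    n_classes = probs.shape[1]
    if n_classes == 2:
        f1 = float(_sk_f1(y_true, y_pred, pos_label=1, zero_division=0))
        auc = roc_auc(probs[:, 1], y_true)
    else:
        f1 = float(_sk_f1(y_true, y_pred, average="macro", zero_division=0))
        auc = macro_roc_auc(probs, y_true, n_classes)
    bucket_ids = np.asarray(bucket_ids)
    per_bucket = {
        b: float(accuracy_score(y_true[bucket_ids == b], y_pred[bucket_ids == b]))
        for b in pd.unique(bucket_ids)
    }
    return MetricReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        f1=f1,
        roc_auc=auc,
        confusion=confusion_matrix(y_true, y_pred, labels=range(n_classes)),
        per_bucket_accuracy=per_bucket,
        n_test=len(y_true),
        task=task,
    )


def evaluate_fold(model, test_set, task: str = "presence") -> MetricReport:
    """Evaluate one fold's trained model on its held-out voxels.

    ``test_set`` is ``(voxels, labels, bucket_ids)``; the model must expose
    ``predict_proba``.
    """
    x, y, buckets = test_set
    probs = model.predict_proba(np.asarray(x))
    return evaluate_predictions(np.asarray(y), probs, np.asarray(buckets), task=task)


def aggregate_folds(
    fold_outputs: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    task: str = "presence",
) -> MetricReport:
    """Pool (concatenate) per-fold test predictions, then compute metrics."""
    if not fold_outputs:
        raise ValueError("no fold outputs to aggregate")
    y = np.concatenate([f[0] for f in fold_outputs])
    p = np.concatenate([f[1] for f in fold_outputs])
    b = np.concatenate([f[2] for f in fold_outputs])
    return evaluate_predictions(y, p, b, task=task)


def intensity_baseline_scores(voxels: np.ndarray, statistic: str = "mean") -> np.ndarray:
    """Single-number-per-voxel baseline scores (mean or max intensity).

    Serves as the no-learning reference against which the 3D-CNN is
    compared; thresholding these scores yields the baseline ROC curve.
    """
    voxels = np.asarray(voxels)
    flat = voxels.reshape(len(voxels), -1)
    if statistic == "mean":
        return flat.mean(axis=1)
    if statistic == "max":
        return flat.max(axis=1)
    raise ValueError(f"unknown statistic {statistic!r}")
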