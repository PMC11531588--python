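"""Fold-plan integrity and metric correctness against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from clamcore.evaluation import (
    UndefinedMetricError,
    aggregate_folds,
    evaluate_fold,
    evaluate_predictions,
    f1_from_pr,
    intensity_baseline_scores,
    macro_roc_auc,
    make_fold_plan,
    roc_auc,
)


def pair_counting_auc(scores, labels):
    """Brute-force ROC-AUC: over all (positive, negative) pairs, count wins
    and half-count ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def synthetic_samples(n_buckets=20, per_bucket=12, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_buckets):
        btype = ["C", "A", "M", "AM"][b % 4]
        for _ in range(per_bucket):
            label = (
                "absence"
                if btype in ("C", "M")
                else rng.choice(["absence", "presence"], p=[0.2, 0.8])
            )
            rows.append((f"{btype}{b // 4 + 1}", label))
    return pd.DataFrame(rows, columns=["bucket_id", "label"])


# --------------------------------------------------------------- fold plan
def test_fold_plan_group_integrity_and_partition():
    samples = synthetic_samples()
    plan = make_fold_plan(samples, n_folds=5, seed=0)
    plan.validate()  # raises on any role leakage / partition failure
    # explicit re-check: a bucket never spans roles within a fold
    for fold in range(5):
        roles = plan.roles(fold)
        per_bucket = pd.DataFrame(
            {"bucket": samples["bucket_id"], "role": roles}
        ).groupby("bucket")["role"].nunique()
        assert (per_bucket == 1).all()
    # union of test sets over folds covers every sample exactly once
    test_hits = sum(plan.mask(f, "test").astype(int) for f in range(5))
    assert (test_hits == 1).all()


def test_fold_plan_role_proportions():
    plan = make_fold_plan(synthetic_samples(), n_folds=5, seed=1)
    for fold in range(5):
        roles = plan.roles(fold)
        n = len(roles)
        # whole-bucket assignment: 3/1/1 folds of 20 buckets -> 60/20/20
        assert abs((roles == "train").mean() - 0.6) < 0.15
        assert abs((roles == "test").mean() - 0.2) < 0.12


def test_fold_plan_stratification_tolerance():
    samples = synthetic_samples(n_buckets=20, per_bucket=30, seed=3)
    plan = make_fold_plan(samples, n_folds=5, seed=3)
    global_frac = (samples["label"] == "presence").mean()
    for fold in range(5):
        te = plan.mask(fold, "test")
        frac = (samples.loc[te, "label"] == "presence").mean()
        assert abs(frac - global_frac) < 0.2


def test_fold_plan_determinism_and_too_few_buckets():
    s = synthetic_samples()
    p1 = make_fold_plan(s, seed=4)
    p2 = make_fold_plan(s, seed=4)
    assert p1.bucket_fold == p2.bucket_fold
    with pytest.raises(ValueError, match="buckets"):
        make_fold_plan(synthetic_samples(n_buckets=4), n_folds=5)


# ------------------------------------------------------------------ F1
@pytest.mark.parametrize(
    "p,r,expected", [(1.0, 1.0, 1.0), (0.5, 0.5, 0.5), (1.0, 0.0, 0.0)]
)
def test_f1_harmonic_mean(p, r, expected):
    assert f1_from_pr(p, r) == pytest.approx(expected)


def test_f1_undefined_at_zero_zero_warns():
    with pytest.warns(UserWarning):
        assert f1_from_pr(0.0, 0.0) == 0.0


def test_f1_rejects_out_of_range():
    with pytest.raises(ValueError):
        f1_from_pr(1.2, 0.5)


# ------------------------------------------------------------------ AUC
def test_roc_auc_perfect_and_null():
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    rng = np.random.default_rng(0)
    scores = rng.random(4000)
    labels = rng.integers(0, 2, 4000)
    assert abs(roc_auc(scores, labels) - 0.5) < 0.03


def test_roc_auc_matches_pair_counting_oracle(rng):
    for _ in range(30):
        n = int(rng.integers(4, 11))
        scores = rng.integers(0, 4, size=n).astype(float)  # forces ties
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if len(np.unique(labels)) < 2:
            continue
        assert roc_auc(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels)
        )


def test_roc_auc_invariant_under_monotone_transform(rng):
    scores = rng.random(50)
    labels = rng.integers(0, 2, 50)
    a = roc_auc(scores, labels)
    assert roc_auc(np.exp(3 * scores) + 7, labels) == pytest.approx(a)


def test_roc_auc_single_class_errors():
    with pytest.raises(UndefinedMetricError):
        roc_auc([0.1, 0.9], [1, 1])


def test_macro_auc_equals_mean_of_per_class(rng):
    n = 60
    labels = rng.integers(0, 3, n)
    probs = rng.random((n, 3))
    probs /= probs.sum(axis=1, keepdims=True)
    expected = np.mean(
        [roc_auc(probs[:, c], (labels == c).astype(int)) for c in range(3)]
    )
    assert macro_roc_auc(probs, labels, 3) == pytest.approx(expected)


def test_macro_auc_missing_class_errors():
    probs = np.full((4, 3), 1 / 3)
    with pytest.raises(UndefinedMetricError):
        macro_roc_auc(probs, np.array([0, 0, 1, 1]), 3)


# ------------------------------------------------------------ evaluation
def _onehot(labels, n):
    out = np.full((len(labels), n), 0.05)
    out[np.arange(len(labels)), labels] = 0.9
    return out / out.sum(axis=1, keepdims=True)


def test_perfect_classifier_metrics():
    y = np.array([0, 1, 2, 0, 1, 2])
    rep = evaluate_predictions(y, _onehot(y, 3), np.array(["B1"] * 6), task="count")
    assert rep.accuracy == 1.0
    assert rep.f1 == 1.0  # macro-F1 of a perfect 3-class classifier
    off_diag = rep.confusion - np.diag(np.diag(rep.confusion))
    assert off_diag.sum() == 0


def test_constant_classifier_macro_f1_closed_form():
    # constant prediction of class 0 on balanced 3-class data:
    # class 0 has precision 1/3, recall 1 -> F1 0.5; others 0 -> macro 1/6
    y = np.array([0, 1, 2] * 4)
    probs = _onehot(np.zeros(12, dtype=int), 3)
    rep = evaluate_predictions(y, probs, np.array(["B1"] * 12), task="count")
    assert rep.f1 == pytest.approx(1 / 6)


def test_confusion_row_sums_and_per_bucket_accuracy():
    y = np.array([0, 0, 1, 1, 1, 0])
    pred = np.array([0, 1, 1, 1, 0, 0])
    buckets = np.array(["B1", "B1", "B1", "B2", "B2", "B2"])
    rep = evaluate_predictions(y, _onehot(pred, 2), buckets)
    np.testing.assert_array_equal(rep.confusion.sum(axis=1), [3, 3])
    assert rep.per_bucket_accuracy["B1"] == pytest.approx(2 / 3)
    assert rep.per_bucket_accuracy["B2"] == pytest.approx(2 / 3)


def test_pooled_accuracy_is_test_size_weighted_mean():
    y1, p1 = np.array([0, 1, 1]), _onehot(np.array([0, 1, 0]), 2)
    y2, p2 = np.array([0, 0, 1, 1, 1]), _onehot(np.array([0, 0, 1, 1, 1]), 2)
    b1, b2 = np.array(["B1"] * 3), np.array(["B2"] * 5)
    pooled = aggregate_folds([(y1, p1, b1), (y2, p2, b2)])
    acc1 = evaluate_predictions(y1, p1, b1).accuracy
    acc2 = evaluate_predictions(y2, p2, b2).accuracy
    assert pooled.accuracy == pytest.approx((3 * acc1 + 5 * acc2) / 8)


def test_evaluate_fold_wraps_model_predictions():
    class Stub:
        def predict_proba(self, x):
            n = len(x)
            out = np.full((n, 2), 0.1)
            out[np.arange(n), np.arange(n) % 2] = 0.9
            return out / out.sum(axis=1, keepdims=True)

    y = np.array([0, 1, 0, 1])
    rep = evaluate_fold(Stub(), (np.zeros((4, 2, 2, 2)), y, ["B1"] * 4))
    assert rep.accuracy == 1.0 and rep.n_test == 4


def test_empty_test_set_errors():
    with pytest.raises(ValueError):
        evaluate_predictions(np.array([]), np.empty((0, 2)), np.array([]))


def test_intensity_baseline_scores(rng):
    voxels = rng.random((5, 4, 4, 6))
    means = intensity_baseline_scores(voxels, "mean")
    maxes = intensity_baseline_scores(voxels, "max")
    assert means.shape == maxes.shape == (5,)
    np.testing.assert_allclose(means, voxels.reshape(5, -1).mean(axis=1))
    assert np.all(maxes >= means)
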