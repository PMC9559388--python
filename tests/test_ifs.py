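"""SMOTE, evaluation metrics, and the incremental-selection loop."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from mutclass import (
    FeatureMatrix,
    RankedList,
    compute_metrics,
    evaluate_prefix,
    multiclass_mcc,
    run_ifs,
    select_feasible,
    smote_balance,
)
from mutclass.ifs import IFSResult, MetricsReport
from conftest import make_informative_matrix


# ------------------------------------------------------------------ SMOTE


def test_smote_balanced_input_unchanged():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 3))
    y = np.array(["a"] * 10 + ["b"] * 10)
    Xb, yb = smote_balance(X, y, seed=1)
    np.testing.assert_array_equal(Xb, X)
    np.testing.assert_array_equal(yb, y)


def test_smote_upsamples_to_majority():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 4))
    y = np.array(["a"] * 10 + ["b"] * 30)
    Xb, yb = smote_balance(X, y, seed=2)
    assert (yb == "a").sum() == 30 and (yb == "b").sum() == 30
    # originals retained unchanged at the front
    np.testing.assert_array_equal(Xb[:40], X)


def test_smote_synthetic_points_between_generators():
    rng = np.random.default_rng(2)
    X = np.vstack([rng.normal(size=(12, 5)), rng.normal(5.0, 1.0, size=(100, 5))])
    y = np.array(["m"] * 12 + ["M"] * 100)
    Xb, yb = smote_balance(X, y, k_neighbors=5, seed=3)
    minority = X[:12]
    synth = Xb[112:]
    assert len(synth) == 88
    lo, hi = minority.min(axis=0), minority.max(axis=0)
    # each synthetic point is a convex combination of two minority points,
    # hence inside the minority bounding box coordinatewise
    assert (synth >= lo - 1e-12).all() and (synth <= hi + 1e-12).all()


def test_smote_singleton_class_is_an_error():
    X = np.zeros((5, 2))
    y = np.array(["a", "a", "a", "a", "b"])
    with pytest.raises(ValueError, match="stratification"):
        smote_balance(X, y)


def test_smote_deterministic():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 3))
    y = np.array(["a"] * 8 + ["b"] * 22)
    out1 = smote_balance(X, y, seed=7)
    out2 = smote_balance(X, y, seed=7)
    np.testing.assert_array_equal(out1[0], out2[0])


# ---------------------------------------------------------------- metrics


def test_perfect_prediction_metrics_all_one():
    y = ["a", "b", "c", "a", "b", "c"]
    rep = compute_metrics(y, y, ["a", "b", "c"])
    assert rep.acc == rep.mcc == rep.macro_f1 == rep.weighted_f1 == 1.0
    assert all(f1 == 1.0 for _, _, f1 in rep.per_class.values())


def test_f1_from_precision_and_recall():
    # one class with precision 1/2 and recall 1/4 -> F1 = 1/3
    y_true = ["a"] * 4 + ["b"] * 4
    y_pred = ["a", "b", "b", "b", "a", "b", "b", "b"]
    rep = compute_metrics(y_true, y_pred, ["a", "b"])
    precision, recall, f1 = rep.per_class["a"]
    assert precision == 0.5 and recall == 0.25
    assert f1 == pytest.approx(1 / 3)


def test_equal_supports_weighted_equals_macro():
    y_true = ["a", "a", "b", "b", "c", "c"]
    y_pred = ["a", "b", "b", "c", "c", "c"]
    rep = compute_metrics(y_true, y_pred, ["a", "b", "c"])
    assert rep.weighted_f1 == pytest.approx(rep.macro_f1)


def test_weighted_f1_is_support_weighted_mean():
    y_true = ["a"] * 6 + ["b"] * 2
    y_pred = ["a"] * 5 + ["b"] * 3
    rep = compute_metrics(y_true, y_pred, ["a", "b"])
    f1s = {c: f1 for c, (_, _, f1) in rep.per_class.items()}
    expected = (6 * f1s["a"] + 2 * f1s["b"]) / 8
    assert rep.weighted_f1 == pytest.approx(expected)


def test_mcc_covariance_form_matches_closed_form_fixture():
    confusion = np.array([[5, 1, 0], [1, 3, 1], [0, 2, 4]])
    classes = ["x", "y", "z"]
    y_true, y_pred = [], []
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            y_true += [ci] * confusion[i, j]
            y_pred += [cj] * confusion[i, j]
    got = multiclass_mcc(y_true, y_pred, classes)
    ref = matthews_corrcoef(y_true, y_pred)
    assert got == pytest.approx(ref, abs=1e-12)


def test_mcc_matches_sklearn_on_random_confusions():
    rng = np.random.default_rng(0)
    for _ in range(200):
        k = int(rng.integers(2, 7))
        classes = [f"c{i}" for i in range(k)]
        conf = rng.integers(0, 12, size=(k, k))
        conf[np.arange(k), np.arange(k)] += 1   # nonempty diagonal
        y_true, y_pred = [], []
        for i in range(k):
            for j in range(k):
                y_true += [classes[i]] * conf[i, j]
                y_pred += [classes[j]] * conf[i, j]
        got = multiclass_mcc(y_true, y_pred, classes)
        ref = matthews_corrcoef(y_true, y_pred)
        assert got == pytest.approx(ref, abs=1e-12)


def test_binary_mcc_equals_classic_formula():
    rng = np.random.default_rng(5)
    y_true = rng.integers(0, 2, 200)
    y_pred = rng.integers(0, 2, 200)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    classic = (tp * tn - fp * fn) / np.sqrt(
        (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    got = multiclass_mcc(list(y_true), list(y_pred), [0, 1])
    assert got == pytest.approx(classic, abs=1e-12)


def test_metrics_input_validation():
    with pytest.raises(ValueError, match="empty"):
        compute_metrics([], [], ["a"])
    with pytest.raises(ValueError, match="lengths"):
        compute_metrics(["a"], ["a", "b"], ["a", "b"])
    with pytest.raises(ValueError, match="declared"):
        compute_metrics(["a"], ["z"], ["a", "b"])


# ------------------------------------------------------- CV and the loop


def test_separable_prefix_scores_perfectly():
    rng = np.random.default_rng(6)
    n = 80
    y = np.array(["p"] * 40 + ["q"] * 40)
    sep = np.concatenate([np.zeros(40), np.ones(40)])
    values = np.column_stack([sep, rng.normal(size=n)])
    fm = FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_names=["sep", "noise"],
        feature_types=["enrichment"] * 2,
        values=values,
    )
    rep = evaluate_prefix(fm, y, ["sep"], classifier="dt", folds=5, seed=0)
    assert rep.weighted_f1 == 1.0


def test_evaluate_prefix_deterministic():
    fm, y = make_informative_matrix(120, 3, 5, 3, seed=9)
    a = evaluate_prefix(fm, y, fm.feature_names[:4], classifier="rf",
                        folds=5, seed=3)
    b = evaluate_prefix(fm, y, fm.feature_names[:4], classifier="rf",
                        folds=5, seed=3)
    assert a.weighted_f1 == b.weighted_f1 and a.mcc == b.mcc


def test_unknown_classifier_tag():
    fm, y = make_informative_matrix(60, 2, 2, 2, seed=0)
    with pytest.raises(ValueError, match="classifier tag"):
        evaluate_prefix(fm, y, fm.feature_names[:2], classifier="mlp", folds=3)


def test_noise_prefix_stays_near_chance_level():
    """Leakage regression at unit scale: noise features, 4 balanced
    classes -> pooled weighted F1 near 0.25."""
    scores = []
    for seed in range(3):
        rng = np.random.default_rng(200 + seed)
        n = 200
        y = np.repeat([f"c{i}" for i in range(4)], n // 4)
        values = rng.normal(size=(n, 10))
        fm = FeatureMatrix(
            sample_ids=[f"s{i}" for i in range(n)],
            feature_names=[f"z{j}" for j in range(10)],
            feature_types=["enrichment"] * 10,
            values=values,
        )
        rep = evaluate_prefix(fm, y, fm.feature_names, classifier="dt",
                              folds=5, seed=seed)
        scores.append(rep.weighted_f1)
    assert abs(float(np.mean(scores)) - 0.25) <= 0.08


def test_ifs_grid_contract_and_bookkeeping():
    fm, y = make_informative_matrix(100, 4, 8, 2, seed=10, shift=2.5)
    ranked = RankedList(method="gbdt", features=list(fm.feature_names),
                        scores=list(range(12, 0, -1)))
    res = run_ifs(fm, y, ranked, classifier="dt", step=5, folds=4, seed=1)
    assert [s for s, _ in res.rows] == [5, 10, 12]
    best = max(rep.weighted_f1 for _, rep in res.rows)
    assert res.optimal_metrics.weighted_f1 == best
    assert res.optimal_size == min(
        s for s, rep in res.rows if rep.weighted_f1 == best
    )
    assert res.feasible_size <= res.optimal_size


def test_ifs_rejects_bad_input():
    fm, y = make_informative_matrix(60, 2, 2, 2, seed=0)
    ranked = RankedList(method="gbdt", features=list(fm.feature_names),
                        scores=[1.0] * 4)
    with pytest.raises(ValueError, match="step"):
        run_ifs(fm, y, ranked, step=0)
    with pytest.raises(ValueError, match="empty"):
        run_ifs(fm, y, RankedList(method="gbdt", features=[], scores=[]))


def _report(wf1: float) -> MetricsReport:
    return MetricsReport(per_class={}, acc=wf1, mcc=0.0,
                         macro_f1=wf1, weighted_f1=wf1, support={})


def test_select_feasible_plateau_and_zero_delta():
    rows = [(5, _report(0.50)), (10, _report(0.80)), (15, _report(0.82)),
            (20, _report(0.83)), (25, _report(0.83))]
    res = IFSResult(method="gbdt", classifier="svm", step=5, rows=rows,
                    optimal_size=20, optimal_metrics=rows[3][1])
    assert select_feasible(res, delta=0.0) == 20
    # plateau onset: first prefix within 0.05 of the 0.83 maximum
    assert select_feasible(res, delta=0.05) == 10
    assert select_feasible(res, delta=0.05) <= res.optimal_size
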