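"""Evaluation machinery: metrics, ROC, confidence intervals, learning curves."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from myoscreen import (
    bootstrap_ci,
    confusion,
    hanley_mcneil_ci,
    learning_curve,
    multiclass_metrics,
    roc_ovr,
    wilson_ci,
)


def brute_force_auc(scores, positives):
    """All-pairs concordance count: the independent AUC oracle."""
    pos = scores[positives]
    neg = scores[~positives]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_perfect_predictions_score_one():
    y = np.array([0, 1, 2, 3, 4] * 4)
    out = multiclass_metrics(y, y, labels=range(5))
    assert out["accuracy"] == 1.0
    assert out["f1_weighted"] == 1.0
    assert all(v == 1.0 for v in out["per_class_accuracy"].values())


def test_constant_predictor_hits_chance_on_balanced_data():
    y = np.array([0, 1, 2, 3, 4] * 10)
    pred = np.zeros_like(y)
    out = multiclass_metrics(y, pred, labels=range(5))
    assert out["accuracy"] == pytest.approx(0.2)


def test_three_class_toy_matrix_hand_count():
    # confusion [[5,0,0],[1,4,0],[0,0,5]] -> accuracy 14/15
    y_true = [0] * 5 + [1] * 5 + [2] * 5
    y_pred = [0] * 5 + [0] + [1] * 4 + [2] * 5
    out = multiclass_metrics(y_true, y_pred, labels=range(3))
    assert out["accuracy"] == pytest.approx(14 / 15)
    matrix = confusion(y_true, y_pred, labels=range(3))
    assert matrix.tolist() == [[5, 0, 0], [1, 4, 0], [0, 0, 5]]


def test_weighted_f1_equals_support_weighted_mean_of_per_class_f1():
    rng = np.random.default_rng(0)
    y_true = rng.integers(0, 5, 300)
    y_pred = np.where(rng.random(300) < 0.7, y_true, rng.integers(0, 5, 300))
    ours = multiclass_metrics(y_true, y_pred, labels=range(5))["f1_weighted"]
    per_class = f1_score(y_true, y_pred, labels=range(5), average=None, zero_division=0)
    support = np.bincount(y_true, minlength=5)
    assert ours == pytest.approx(np.average(per_class, weights=support))


def test_confusion_row_sums_equal_class_supports():
    rng = np.random.default_rng(1)
    y_true = rng.integers(0, 5, 200)
    y_pred = rng.integers(0, 5, 200)
    matrix = confusion(y_true, y_pred, labels=range(5))
    assert matrix.sum() == 200
    assert np.array_equal(matrix.sum(axis=1), np.bincount(y_true, minlength=5))


def test_confusion_rejects_unknown_labels():
    with pytest.raises(ValueError, match="unknown label"):
        roc_ovr(["Nonsense"], np.ones((1, 5)), labels=["A", "B", "C", "D", "E"])


def test_roc_perfect_and_reversed_scores():
    y = np.array([0] * 5 + [1] * 5)
    scores = np.zeros((10, 2))
    scores[:5, 0] = 1.0
    scores[5:, 1] = 1.0
    out = roc_ovr(y, scores, labels=[0, 1])
    assert out["mean_auc"] == 1.0
    reversed_out = roc_ovr(y, -scores, labels=[0, 1])
    assert reversed_out["mean_auc"] == 0.0


def test_roc_matches_brute_force_concordance_and_sklearn():
    rng = np.random.default_rng(2)
    n = 180
    y = rng.integers(0, 5, n)
    scores = rng.normal(size=(n, 5)) + np.eye(5)[y] * 1.5
    scores = np.round(scores, 1)  # force ties to exercise the tie handling
    out = roc_ovr(y, scores, labels=range(5))
    for i in range(5):
        expected = brute_force_auc(scores[:, i], y == i)
        assert out["per_class_auc"][str(i)] == pytest.approx(expected, abs=1e-12)
    sk_per_class = [roc_auc_score(y == i, scores[:, i]) for i in range(5)]
    assert out["mean_auc"] == pytest.approx(np.mean(sk_per_class), abs=1e-12)


def test_roc_random_scores_near_half():
    rng = np.random.default_rng(3)
    n = 10000
    y = rng.integers(0, 5, n)
    scores = rng.normal(size=(n, 5))
    assert roc_ovr(y, scores, labels=range(5))["mean_auc"] == pytest.approx(0.5, abs=0.02)


def test_roc_excludes_empty_class_with_warning():
    y = np.array([0, 0, 1, 1])
    scores = np.random.default_rng(0).normal(size=(4, 3))
    with pytest.warns(UserWarning, match="excluded"):
        out = roc_ovr(y, scores, labels=[0, 1, 2])
    assert np.isnan(out["per_class_auc"]["2"])


def test_bootstrap_ci_reproducible_and_degenerate():
    y_true = np.array([0, 1] * 100)
    y_pred = y_true.copy()
    constant = bootstrap_ci(lambda t, p: 1.0, y_true, y_pred, B=200, seed=0)
    assert (constant.lower, constant.upper) == (1.0, 1.0)
    a = bootstrap_ci(lambda t, p: np.mean(t == p), y_true, y_pred, B=1000, seed=42)
    b = bootstrap_ci(lambda t, p: np.mean(t == p), y_true, y_pred, B=1000, seed=42)
    assert (a.lower, a.upper) == (b.lower, b.upper)
    assert a.method == "bootstrap_percentile"


def test_bootstrap_ci_width_matches_normal_approximation():
    rng = np.random.default_rng(7)
    n, acc = 200, 0.95
    y_true = np.zeros(n, dtype=int)
    y_pred = np.where(rng.random(n) < acc, 0, 1)
    observed = float(np.mean(y_true == y_pred))
    ci = bootstrap_ci(lambda t, p: np.mean(t == p), y_true, y_pred, B=1000, seed=1)
    assert ci.lower <= observed <= ci.upper
    expected_width = 2 * 1.96 * np.sqrt(observed * (1 - observed) / n)
    width = ci.upper - ci.lower
    assert width == pytest.approx(expected_width, rel=0.30)


def test_wilson_matches_statsmodels_and_boundaries():
    lower, upper = wilson_ci(95, 100)
    sm_lower, sm_upper = proportion_confint(95, 100, alpha=0.05, method="wilson")
    assert lower == pytest.approx(sm_lower, abs=1e-12)
    assert upper == pytest.approx(sm_upper, abs=1e-12)
    assert wilson_ci(100, 100).upper == 1.0
    assert wilson_ci(0, 50).lower == 0.0
    with pytest.raises(ValueError):
        wilson_ci(5, 0)


def test_wilson_contains_point_and_narrows_with_n():
    widths = []
    for n in (20, 80, 320, 1280):
        successes = int(round(0.9 * n))
        ci = wilson_ci(successes, n)
        assert ci.lower <= successes / n <= ci.upper
        widths.append(ci.upper - ci.lower)
    assert all(b < a for a, b in zip(widths, widths[1:]))


def test_hanley_mcneil_closed_form():
    degenerate = hanley_mcneil_ci(1.0, 50, 50)
    assert (degenerate.lower, degenerate.upper) == (1.0, 1.0)

    auc, n_pos, n_neg = 0.5, 40, 40
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    se = np.sqrt(
        (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2))
        / (n_pos * n_neg)
    )
    ci = hanley_mcneil_ci(auc, n_pos, n_neg)
    assert ci.lower == pytest.approx(auc - 1.959963984540054 * se, abs=1e-9)
    assert ci.upper == pytest.approx(auc + 1.959963984540054 * se, abs=1e-9)

    wide = hanley_mcneil_ci(0.99, 2, 2)
    assert 0.0 <= wide.lower <= wide.upper <= 1.0
    with pytest.raises(ValueError):
        hanley_mcneil_ci(0.9, 0, 10)


@pytest.fixture(scope="module")
def toy_learnable():
    rng = np.random.default_rng(5)
    n = 400
    y = rng.integers(0, 3, n)
    X = rng.normal(size=(n, 4))
    X[:, :3] += np.eye(3)[y] * 3.0
    return X, y


def test_learning_curve_shape_and_single_fold_sd(toy_learnable):
    X, y = toy_learnable
    model = RandomForestClassifier(n_estimators=20, max_depth=4, random_state=0)
    curve = learning_curve(model, X, y, sizes=[30, 100, 250], folds=1, seed=0)
    assert curve["size"].tolist() == [30, 100, 250]
    assert (curve["validation_accuracy_sd"] == 0.0).all()
    assert (curve["folds"] == 1).all()


def test_learning_curve_validation_improves_with_size(toy_learnable):
    X, y = toy_learnable
    model = RandomForestClassifier(n_estimators=20, max_depth=4, random_state=0)
    curve = learning_curve(model, X, y, sizes=[20, 80, 300], folds=3, seed=1)
    first, last = curve.iloc[0], curve.iloc[-1]
    band = first["validation_accuracy_sd"] + last["validation_accuracy_sd"]
    assert last["validation_accuracy_mean"] >= first["validation_accuracy_mean"] - band


def test_learning_curve_skips_sizes_below_class_count(toy_learnable):
    X, y = toy_learnable
    model = RandomForestClassifier(n_estimators=5, random_state=0)
    with pytest.warns(UserWarning, match="skipped"):
        curve = learning_curve(model, X, y, sizes=[2, 50], folds=1, seed=0)
    assert curve["size"].tolist() == [50]


def test_evaluate_model_report_is_internally_consistent(toy_learnable):
    X, y = toy_learnable
    model = RandomForestClassifier(n_estimators=30, max_depth=5, random_state=0).fit(X, y)
    from myoscreen import evaluate_model

    report = evaluate_model(model, "rf", X, y, class_names=("A", "B", "C"), B=100, seed=0)
    assert report.confusion_matrix.sum() == report.n == len(y)
    assert 0.0 <= report.metrics["accuracy"] <= 1.0
    assert set(report.per_class_auc) == {"A", "B", "C"}
    for name, ci in report.intervals.items():
        assert ci.lower <= ci.upper, name
    wilson = report.intervals["accuracy_wilson"]
    assert wilson.lower <= report.metrics["accuracy"] <= wilson.upper
    hm = report.intervals["mean_auc_hanley_mcneil"]
    assert hm.lower <= report.mean_auc <= hm.upper
    import json

    json.dumps(report.to_dict())  # must be serializable for report artifacts


def test_empty_inputs_are_errors():
    with pytest.raises(ValueError):
        multiclass_metrics([], [])
    with pytest.raises(ValueError):
        bootstrap_ci(lambda t: 1.0, np.array([]))
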