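"""Cross-validation, diagnostic metrics with exact CIs, PCA, repeatability."""

import numpy as np
import pytest
from scipy import stats

from enosedx import (
    ConfusionMatrix,
    clopper_pearson,
    confusion_metrics,
    cross_validate,
    pca_scores,
    repeatability_index,
    simulate_feature_matrix,
)


def test_reported_confusion_matrix_metrics():
    """The published 10-fold CV matrix: S-row (47, 20), PCa-row (7, 90)."""
    cm = ConfusionMatrix(tp=90, fn=20, tn=47, fp=7)
    m = confusion_metrics(cm)
    assert m.sensitivity.percent == 82  # 90/110 = 81.8%
    assert m.specificity.percent == 87  # 47/54 = 87.0%
    assert m.accuracy.point == pytest.approx(137 / 164)
    assert m.accuracy.percent == 84  # exact 83.5% rounds to 84


def test_perfect_classification_metrics():
    m = confusion_metrics(ConfusionMatrix(tp=10, fn=0, tn=8, fp=0))
    for est in (m.accuracy, m.sensitivity, m.specificity):
        assert est.point == 1.0
        assert est.upper == 1.0


def test_half_half_matrix_closed_form_ci():
    m = confusion_metrics(ConfusionMatrix(1, 1, 1, 1))
    for est in (m.sensitivity, m.specificity):
        assert est.point == 0.5
        # Clopper-Pearson bounds for 1 success in 2 trials are beta quantiles
        assert est.lower == pytest.approx(stats.beta.ppf(0.025, 1, 2))
        assert est.upper == pytest.approx(stats.beta.ppf(0.975, 2, 1))
    assert m.accuracy.point == 0.5


def test_zero_denominator_reported_undefined():
    m = confusion_metrics(ConfusionMatrix(tp=0, fn=0, tn=5, fp=2))
    assert m.sensitivity is None
    assert m.specificity is not None


def test_confusion_matrix_validation_and_frame():
    with pytest.raises(ValueError):
        ConfusionMatrix(-1, 0, 0, 0)
    frame = ConfusionMatrix(tp=90, fn=20, tn=47, fp=7).to_frame()
    assert frame.loc["S", "S"] == 47
    assert frame.loc["S", "PCa"] == 20
    assert frame.loc["PCa", "S"] == 7
    assert frame.loc["PCa", "PCa"] == 90


def test_clopper_pearson_extremes():
    est0 = clopper_pearson(0, 20)
    assert est0.lower == 0.0 and est0.point == 0.0
    est1 = clopper_pearson(20, 20)
    assert est1.upper == 1.0 and est1.point == 1.0
    with pytest.raises(ValueError):
        clopper_pearson(5, 0)


@pytest.mark.parametrize("n,p", [(54, 0.87), (110, 0.82)])
def test_clopper_pearson_coverage_by_simulation(n, p):
    """Empirical 95% coverage at the study's denominators (2000 reps)."""
    rng = np.random.default_rng(42)
    draws = rng.binomial(n, p, size=2000)
    intervals = {k: clopper_pearson(k, n) for k in np.unique(draws)}
    covered = np.array([intervals[k].lower <= p <= intervals[k].upper for k in draws])
    assert covered.mean() >= 0.94


def test_cross_validate_separable_features_perfect():
    X, y = simulate_feature_matrix(60, 4, 6, effect=8.0, seed=0)
    cm, folds = cross_validate(X, y, k=5, seed=0)
    assert cm.fn == 0 and cm.fp == 0
    assert cm.total == 60


def test_cross_validate_fold_sums_match_pooled():
    X, y = simulate_feature_matrix(80, 4, 10, effect=1.5, seed=1)
    cm, folds = cross_validate(X, y, k=8, seed=1)
    assert folds[["tp", "fn", "tn", "fp"]].sum().sum() == cm.total == 80
    assert folds["tp"].sum() == cm.tp
    assert folds["n_test"].sum() == 80


def test_cross_validate_deterministic_under_seed():
    X, y = simulate_feature_matrix(60, 3, 8, effect=1.2, seed=2)
    cm1, _ = cross_validate(X, y, k=5, seed=7)
    cm2, _ = cross_validate(X, y, k=5, seed=7)
    assert cm1 == cm2


def test_cross_validate_permuted_labels_near_majority_rate():
    X, _ = simulate_feature_matrix(164, 10, 140, effect=2.0, seed=3)
    rng = np.random.default_rng(3)
    y = rng.permutation(np.array(["PCa"] * 110 + ["S"] * 54))
    cm, _ = cross_validate(X, y, k=10, seed=3)
    acc = (cm.tp + cm.tn) / cm.total
    assert abs(acc - 110 / 164) < 0.12


def test_cross_validate_rejects_tiny_minority():
    X, y = simulate_feature_matrix(20, 2, 4, seed=4)
    y = np.array(["PCa"] * 17 + ["S"] * 3)
    with pytest.raises(ValueError, match="lower k"):
        cross_validate(X, y, k=10, seed=0)


def test_pca_duplicated_rows_identical_scores():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(10, 6))
    X = np.vstack([X, X[0]])
    res = pca_scores(X, n_components=2)
    np.testing.assert_allclose(res.scores[0], res.scores[-1], atol=1e-10)


def test_pca_two_feature_hand_example_matches_eigendecomposition():
    rng = np.random.default_rng(5)
    X = rng.multivariate_normal([0, 0], [[2.0, 1.2], [1.2, 1.0]], size=200)
    res = pca_scores(X, n_components=2, standardize=False)
    Xc = X - X.mean(axis=0)
    evals, evecs = np.linalg.eigh(np.cov(Xc.T))
    order = np.argsort(evals)[::-1]
    np.testing.assert_allclose(res.explained_variance, evals[order], rtol=1e-8)
    for j in range(2):
        v = evecs[:, order[j]]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        np.testing.assert_allclose(np.abs(res.loadings[j]), np.abs(v), atol=1e-8)
        np.testing.assert_allclose(res.scores[:, j], Xc @ v, atol=1e-8)


def test_pca_explained_variance_bounded_by_total():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(30, 8))
    res = pca_scores(X, n_components=3, standardize=False)
    total = np.var(X - X.mean(axis=0), axis=0, ddof=1).sum()
    assert res.explained_variance.sum() <= total + 1e-9
    assert np.all(res.explained_variance_ratio <= 1.0)


def test_pca_rejects_too_many_components():
    with pytest.raises(ValueError):
        pca_scores(np.ones((3, 2)) + np.eye(3, 2), n_components=5)


def test_repeatability_identical_repeats_zero():
    scores = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
    ids = ["a", "a", "b", "b"]
    assert repeatability_index(scores, ids) == pytest.approx(0.0)


def test_repeatability_shuffled_labels_near_one():
    rng = np.random.default_rng(7)
    scores = rng.normal(size=(60, 2))
    ids = np.repeat([f"s{i}" for i in range(20)], 3)
    vals = [
        repeatability_index(scores, rng.permutation(ids)) for _ in range(20)
    ]
    assert abs(np.mean(vals) - 1.0) < 0.1


def test_repeatability_requires_repeats():
    scores = np.zeros((4, 2))
    with pytest.raises(ValueError):
        repeatability_index(scores, ["a", "b", "c", "d"])
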