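"""PLS engine and evaluation machinery against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sportfuse import (
    class_metrics,
    compare_models,
    cross_validate,
    fit_pls,
    kennard_stone,
    one_hot,
    permutation_test,
    plsda_predict,
    reg_metrics,
)
from sportfuse.plscore import (
    RegReport,
    cv_class_accuracy,
    cv_q2,
    venetian_folds,
)


# ------------------------------------------------------------ Kennard-Stone

def test_kennard_stone_points_on_a_line():
    pts = np.array([[0.0], [1.0], [2.0], [10.0]])
    train, test = kennard_stone(pts, 2)
    assert set(train.tolist()) == {0, 3}
    assert set(test.tolist()) == {1, 2}


def test_kennard_stone_full_train_and_determinism(small_dataset):
    n = small_dataset.n_samples
    train, test = kennard_stone(small_dataset, n)
    assert len(test) == 0 and len(train) == n
    a = kennard_stone(small_dataset, 20)
    b = kennard_stone(small_dataset, 20)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def test_kennard_stone_duplicate_rows_tie_break():
    pts = np.array([[0.0], [0.0], [5.0], [5.0]])
    train, _ = kennard_stone(pts, 2)
    assert train.tolist() == [0, 2]  # lowest-index resolution


# ------------------------------------------------------------------- PLS

def test_single_factor_recovery():
    """One LV suffices when y is proportional to one of orthogonal columns."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 6))
    X = np.linalg.qr(X - X.mean(axis=0))[0]  # centered, orthogonal columns
    y = 3.0 * X[:, 2]
    model = fit_pls(X, y, n_lv=1)
    assert np.allclose(model.predict(X).ravel(), y, atol=1e-8)


def test_full_rank_pls_equals_least_squares():
    """At full rank, PLS reproduces the normal-equations solution."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        X = rng.normal(size=(8, 5))
        Y = rng.normal(size=(8, 2))
        model = fit_pls(X, Y, n_lv=5)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        B = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        assert np.max(np.abs(model.coefficients - B)) < 1e-6


def test_duplicated_column_blocks_leave_predictions_unchanged():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(15, 6))
    y = rng.normal(size=15)
    m1 = fit_pls(X, y, n_lv=3)
    m2 = fit_pls(np.hstack([X, X]), y, n_lv=3)
    assert np.allclose(m1.predict(X), m2.predict(np.hstack([X, X])), atol=1e-8)


def test_score_columns_orthogonal(small_dataset):
    y = small_dataset.content
    model = fit_pls(small_dataset.intensities, y, n_lv=5)
    T = model.scores
    gram = T.T @ T
    off = gram - np.diag(np.diag(gram))
    assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))


def test_rank_exhaustion_truncates():
    X = np.outer(np.arange(10.0), np.ones(4))  # rank 1 after centering
    y = np.arange(10.0)
    model = fit_pls(X, y, n_lv=3)
    assert model.n_lv == 1


def test_zero_variance_response_rejected():
    X = np.random.default_rng(0).normal(size=(10, 4))
    with pytest.raises(ValueError):
        fit_pls(X, np.ones(10), n_lv=2)


# --------------------------------------------------------- cross-validation

def test_cv_recovers_true_dimension():
    rng = np.random.default_rng(1)
    latent = rng.normal(size=(35, 2))
    X = latent @ rng.normal(size=(2, 10)) + 0.0
    y = latent @ np.array([1.0, -2.0])
    cv = cross_validate(X, y, max_lv=6)
    assert cv.chosen_n_lv == 2


def test_venetian_folds_partition():
    folds = venetian_folds(14, 7)
    counts = np.bincount(folds, minlength=7)
    assert np.all(counts == 2)
    assert len(folds) == 14


@settings(derandomize=True, max_examples=20)
@given(st.integers(8, 60), st.integers(2, 7))
def test_fold_assignment_is_partition(n, k):
    folds = venetian_folds(n, k)
    assert folds.shape == (n,)
    assert set(folds.tolist()) == set(range(k))


def test_pure_noise_rmsecv_rises_with_model_size():
    """Overfitting: averaged over seeds, large-LV RMSECV exceeds 1-LV."""
    last, first = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 20))
        y = rng.normal(size=30)
        cv = cross_validate(X, y, max_lv=8)
        first.append(cv.rmsecv[0])
        last.append(cv.rmsecv[-1])
    assert np.mean(last) > np.mean(first)


def test_chosen_lv_minimizes_curve(small_dataset):
    cv = cross_validate(small_dataset.intensities, small_dataset.content, max_lv=6)
    assert cv.rmsecv[cv.chosen_n_lv - 1] == pytest.approx(cv.rmsecv.min())


# ------------------------------------------------------------- PLS-DA

def test_plsda_perfect_five_class():
    truth = np.repeat(list("ABCDE"), 4)
    rep = class_metrics(truth, truth)
    assert rep.accuracy == 1.0
    assert np.allclose(rep.sensitivity, 1.0) and np.allclose(rep.specificity, 1.0)


def test_class_metrics_hand_counted_matrix():
    """Confusion [[8,1,1],[0,9,1],[2,0,8]] counted by hand."""
    truth = np.repeat(["a", "b", "c"], 10)
    pred = (["a"] * 8 + ["b"] + ["c"]
            + ["b"] * 9 + ["c"]
            + ["a"] * 2 + ["c"] * 8)
    rep = class_metrics(truth, np.array(pred))
    assert rep.accuracy == pytest.approx(25 / 30)
    assert np.allclose(rep.sensitivity, [0.8, 0.9, 0.8])
    assert rep.specificity[0] == pytest.approx(18 / 20)
    assert rep.confusion.sum() == 30


def test_constant_predictor_in_balanced_five_class():
    truth = np.repeat([1, 2, 3, 4, 5], 6)
    pred = np.ones_like(truth)
    rep = class_metrics(truth, pred, classes=np.array([1, 2, 3, 4, 5]))
    assert rep.accuracy == pytest.approx(0.2)
    assert rep.specificity[0] == 0.0


def test_metrics_recomputable_from_confusion():
    rng = np.random.default_rng(9)
    truth = rng.integers(0, 4, 50)
    pred = rng.integers(0, 4, 50)
    rep = class_metrics(truth, pred, classes=np.arange(4))
    cm = rep.confusion
    assert rep.accuracy == np.trace(cm) / cm.sum()
    for i in range(4):
        tp = cm[i, i]
        assert rep.sensitivity[i] == pytest.approx(tp / cm[i].sum())


def test_unseen_class_at_prediction_rejected(small_dataset):
    Y, classes = one_hot(small_dataset.class_labels)
    model = fit_pls(small_dataset.intensities, Y, n_lv=2)
    with pytest.raises(ValueError):
        plsda_predict(model, small_dataset.intensities, classes[:2])


# --------------------------------------------------------- regression metrics

def test_reg_metrics_arithmetic():
    assert reg_metrics([1, 2, 3], [1, 2, 3]) == {"rmse": 0.0, "r2": 1.0}
    m = reg_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 6.0])
    assert m["rmse"] == pytest.approx(np.sqrt(3.0))
    truth = np.array([1.0, 2.0, 3.0])
    assert reg_metrics(truth, np.full(3, truth.mean()))["r2"] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        reg_metrics([2.0, 2.0], [1.0, 2.0])


# --------------------------------------------------------- permutation test

def test_permutation_single_iteration_formula():
    stat = lambda X, y: 0.5  # noqa: E731  null always >= observed
    res = permutation_test(stat, np.zeros((6, 2)), np.arange(6), n_iter=1, seed=0)
    assert res.p_value == 1.0


def test_permutation_detects_separable_classes():
    rng = np.random.default_rng(2)
    labels = np.repeat(["A", "B"], 20)
    X = rng.normal(size=(40, 10))
    X[labels == "A", :3] += 4.0
    pipe = lambda Xp, yp: cv_class_accuracy(Xp, yp, max_lv=3)  # noqa: E731
    res = permutation_test(pipe, X, labels, n_iter=200, seed=1)
    assert res.p_value <= 0.01


def test_permutation_p_monotone_in_observed_statistic():
    null = np.linspace(0, 1, 99)

    def p_for(obs):
        return (1 + np.sum(null >= obs)) / (len(null) + 1)

    ps = [p_for(o) for o in (0.2, 0.5, 0.9)]
    assert ps[0] >= ps[1] >= ps[2]
    assert all(0 < p <= 1 for p in ps)


def test_permutation_failures_warned_not_silent():
    calls = {"n": 0}

    def flaky(X, y):
        calls["n"] += 1
        if calls["n"] % 2 == 0:
            raise RuntimeError("boom")
        return 0.1

    with pytest.warns(RuntimeWarning, match="excluded"):
        res = permutation_test(flaky, np.zeros((4, 2)), np.arange(4), n_iter=6, seed=0)
    assert res.n_failed > 0
    assert len(res.null) + res.n_failed == 6


# --------------------------------------------------------- model comparison

def test_compare_models_identity_and_errors():
    a = RegReport(r2c=0.9, rmsecv=1.0, r2p=0.8, rmsep=2.0)
    assert all(v == 0.0 for v in compare_models(a, a).values())
    zero = RegReport(r2c=0.9, rmsecv=1.0, r2p=0.8, rmsep=0.0)
    with pytest.raises(ZeroDivisionError):
        compare_models(zero, a)
    with pytest.raises(TypeError):
        compare_models(a, class_metrics([1, 2], [1, 2]))


def test_cv_q2_perfect_signal_is_high():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 8))
    y = X @ rng.normal(size=8)
    assert cv_q2(X, y, max_lv=6) > 0.99
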