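"""Linear and forest regressors, CV machinery, metrics, error tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tractscape as ts

# reference 10-fold results of a published tract-level obesity model,
# used as frozen input for the fold-summary worked example
REFERENCE_FOLD_MSE = [18.54, 22.06, 12.56, 13.07, 13.58, 10.22, 12.81, 16.68, 11.06, 16.36]
REFERENCE_FOLD_R2 = [0.406, 0.011, 0.538, 0.546, 0.559, 0.661, 0.537, 0.485, 0.567, 0.456]
REFERENCE_FOLD_ADJ = [0.400, 0.001, 0.534, 0.541, 0.555, 0.657, 0.533, 0.480, 0.563, 0.451]


def _folds(mses, r2s, adjs):
    return [
        ts.FoldMetrics(i + 1, m, r, a, n_test=100)
        for i, (m, r, a) in enumerate(zip(mses, r2s, adjs))
    ]


def test_linear_recovers_coefficients_when_identifiable():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 5))
    beta = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
    y = X @ beta + 4.0
    model = ts.fit_linear(X, y)
    assert np.allclose(model.coef_, beta, atol=1e-8)
    assert model.intercept_ == pytest.approx(4.0, abs=1e-8)
    assert model.score(X, y) == pytest.approx(1.0)


def test_minimum_norm_solution_interpolates_when_p_exceeds_n():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(20, 100))
    y = rng.normal(size=20)
    model = ts.fit_linear(X, y, ridge=0.0)
    assert np.allclose(model.predict(X), y, atol=1e-8)


def test_huge_ridge_shrinks_to_mean():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(40, 6))
    y = rng.normal(loc=10.0, size=40)
    model = ts.fit_linear(X, y, ridge=1e12)
    assert np.allclose(model.predict(X), y.mean(), atol=1e-3)


def test_nonfinite_inputs_rejected():
    X = np.array([[1.0, np.nan], [2.0, 3.0]])
    with pytest.raises(ValueError, match="finite"):
        ts.fit_linear(X, np.array([1.0, 2.0]))
    with pytest.raises(ValueError, match="finite"):
        ts.fit_forest(X, np.array([1.0, 2.0]))


def test_forest_constant_target_and_determinism():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 4))
    y_const = np.full(30, 7.5)
    model = ts.fit_forest(X, y_const, n_trees=20, seed=0)
    assert np.allclose(model.predict(X), 7.5)

    y = rng.normal(size=30)
    p1 = ts.fit_forest(X, y, n_trees=20, seed=5).predict(X)
    p2 = ts.fit_forest(X, y, n_trees=20, seed=5).predict(X)
    assert np.array_equal(p1, p2)


def test_forest_finds_the_informative_feature():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(300, 100))
    y = 3.0 * X[:, 42] + rng.normal(scale=0.3, size=300)
    model = ts.fit_forest(X, y, n_trees=50, seed=0, max_features=1.0)
    assert int(np.argmax(model.feature_importances_)) == 42


def test_holdout_split_sizes_and_perfect_model():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(1055, 3))
    y = X @ np.array([1.0, 2.0, -1.0]) + 5.0
    metrics = ts.holdout_evaluate(X, y, model_kind="glm", split_fraction=0.8, seed=0)
    assert metrics.n_test == 211  # floor(0.2 * 1055), train gets 844
    assert metrics.r2 == pytest.approx(1.0, abs=1e-9)
    assert metrics.mse == pytest.approx(0.0, abs=1e-12)

    again = ts.holdout_evaluate(X, y, model_kind="glm", split_fraction=0.8, seed=0)
    assert again.mse == metrics.mse and again.r2 == metrics.r2


def test_holdout_rejects_tiny_test_partition():
    X = np.ones((5, 2))
    y = np.arange(5.0)
    with pytest.raises(ValueError):
        ts.holdout_evaluate(X, y, split_fraction=0.9)


def test_kfold_partitions_the_index_set():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(53, 4))
    y = X[:, 0] + rng.normal(size=53)
    cv = ts.kfold_cv(X, y, k=10, model_kind="glm", seed=0)
    sizes = [f.n_test for f in cv.folds]
    assert sum(sizes) == 53
    assert max(sizes) - min(sizes) <= 1
    assert not np.any(np.isnan(cv.oof_predictions))  # every sample predicted once
    assert cv.mean_mse == pytest.approx(np.mean([f.mse for f in cv.folds]))


def test_leave_one_out_and_k_bounds():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(12, 2))
    y = X[:, 0] * 2.0
    cv = ts.kfold_cv(X, y, k=12, model_kind="glm", seed=0)
    assert all(f.n_test == 1 for f in cv.folds)
    assert all(np.isnan(f.r2) for f in cv.folds)  # single-sample R^2 undefined
    assert not np.any(np.isnan(cv.oof_predictions))
    with pytest.raises(ValueError, match="exceeds"):
        ts.kfold_cv(X, y, k=13)
    with pytest.raises(ValueError, match=">= 2"):
        ts.kfold_cv(X, y, k=1)


def test_compute_metrics_worked_examples():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    assert ts.compute_metrics(y, y, p_eff=1) == pytest.approx((0.0, 1.0, 1.0))
    mse, r2, _ = ts.compute_metrics(y, np.full(4, y.mean()), p_eff=1)
    assert r2 == pytest.approx(0.0)

    rng = np.random.default_rng(0)
    actual = rng.normal(size=101)
    # build predictions with R^2 = 0.5 exactly, then check the adjustment
    resid = actual - actual.mean()
    predicted = actual - resid * np.sqrt(0.5 * resid @ resid / (resid @ resid))
    _, r2, adj = ts.compute_metrics(actual, predicted, p_eff=1)
    assert r2 == pytest.approx(0.5)
    assert adj == pytest.approx(1 - 0.5 * 100 / 99, abs=1e-9)


def test_compute_metrics_degenerate_cases():
    with pytest.raises(ValueError, match="zero variance"):
        ts.compute_metrics(np.ones(5), np.zeros(5), p_eff=1)
    # adjustment undefined when n <= p_eff + 1
    _, _, adj = ts.compute_metrics(
        np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 2.5]), p_eff=2
    )
    assert np.isnan(adj)


def test_summarize_folds_reproduces_reference_means():
    folds = _folds(REFERENCE_FOLD_MSE, REFERENCE_FOLD_R2, REFERENCE_FOLD_ADJ)
    mean_mse, mean_r2, mean_adj = ts.summarize_folds(folds)
    assert abs(mean_mse - 14.69) <= 0.005
    assert abs(mean_r2 - 0.477) <= 0.0005
    assert abs(mean_adj - 0.471) <= 0.0005 + 1e-12


def test_summarize_identical_folds():
    folds = _folds([2.0] * 4, [0.5] * 4, [0.4] * 4)
    assert ts.summarize_folds(folds) == pytest.approx((2.0, 0.5, 0.4))


def test_importances_sum_to_100_and_rank_the_signal():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(200, 30))
    y = 4.0 * X[:, 7] + rng.normal(scale=0.5, size=200)
    cv = ts.kfold_cv(X, y, k=5, model_kind="rf", seed=0, n_trees=30, keep_models=True)
    records = ts.feature_importance(cv.models, X, y)
    assert sum(r.importance_pct for r in records) == pytest.approx(100.0, abs=1e-6)
    assert records[0].feature_index == 7
    assert records[0].correlation > 0.9


def test_negative_association_yields_negative_correlation():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(150, 5))
    X[:, 2] = np.arange(150.0)
    y = -X[:, 2] + rng.normal(scale=1.0, size=150)
    cv = ts.kfold_cv(X, y, k=4, model_kind="rf", seed=0, n_trees=20, keep_models=True)
    records = ts.feature_importance(cv.models, X, y)
    rec2 = next(r for r in records if r.feature_index == 2)
    assert rec2.correlation < 0


def test_constant_feature_gets_zero_correlation():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(60, 4))
    X[:, 1] = 3.14
    y = X[:, 0] + rng.normal(size=60)
    cv = ts.kfold_cv(X, y, k=3, model_kind="rf", seed=0, n_trees=10, keep_models=True)
    records = ts.feature_importance(cv.models, X, y)
    rec1 = next(r for r in records if r.feature_index == 1)
    assert rec1.correlation == 0.0


def test_error_analysis_worked_examples():
    table, subsets = ts.error_analysis(
        ["29510124600", "29207470600", "0003"],
        np.array([46.00, 39.80, 40.0]),
        np.array([37.63, 48.32, 40.0]),
        thresholds=(4.0, 2.5),
    )
    by_id = table.set_index("tract_id")["signed_error"]
    assert by_id["29510124600"] == pytest.approx(8.37, abs=1e-12)
    assert by_id["29207470600"] == pytest.approx(-8.52, abs=1e-12)
    assert by_id["0003"] == 0.0
    # ranked by signed error, descending
    assert list(table["signed_error"]) == sorted(table["signed_error"], reverse=True)
    for th, sub in subsets.items():
        assert "0003" not in set(sub["tract_id"])
        assert np.all(sub["signed_error"].abs() >= th)


@given(
    st.lists(
        st.tuples(
            st.floats(min_value=-50, max_value=50),
            st.floats(min_value=-50, max_value=50),
        ),
        min_size=3,
        max_size=40,
    )
)
def test_metric_identities(pairs):
    actual = np.array([a for a, _ in pairs])
    predicted = np.array([p for _, p in pairs])
    if np.var(actual) == 0:
        return
    mse, r2, adj = ts.compute_metrics(actual, predicted, p_eff=1)
    assert mse >= 0
    assert r2 <= 1.0 + 1e-12
    if not np.isnan(adj):
        assert adj <= r2 + 1e-12
    assert (mse == 0) == (r2 == pytest.approx(1.0))


def test_cv_to_frame_display_rounding():
    folds = _folds([1.234, 2.345], [0.1234, 0.2345], [0.1, 0.2])
    cv = ts.CVSummary(
        folds=folds, mean_mse=1.7895, mean_r2=0.17895, mean_adj_r2=0.15,
        oof_predictions=np.zeros(2), y=np.array([1.0, 2.0]),
    )
    frame = cv.to_frame()
    assert list(frame.columns) == ["fold", "mse", "r2", "adj_r2"]
    assert frame.loc[0, "mse"] == 1.23
    assert frame.loc[2, "fold"] == "Mean"
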