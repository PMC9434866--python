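"""PLS1 engine: NIPALS fit, prediction, LOOCV, component choice, metrics."""

import numpy as np
import pytest

from nircarb import (
    CVCurve,
    PLSModel,
    fit_pls,
    loocv_curve,
    predict_pls,
    regression_metrics,
    select_ncomp,
)
from nircarb.errors import DegenerateResponseError, DomainError, ZeroVarianceError


@pytest.fixture
def random_problem():
    rng = np.random.default_rng(17)
    X = rng.standard_normal((20, 10))
    beta = rng.standard_normal(10)
    y = X @ beta + 0.1 * rng.standard_normal(20)
    return X, y


def brute_force_loocv(X, y, max_comp):
    """Independent oracle: refit from scratch for every (left-out, a)."""
    n = len(y)
    press = np.zeros(max_comp)
    for a in range(1, max_comp + 1):
        for i in range(n):
            mask = np.arange(n) != i
            model = fit_pls(X[mask], y[mask], a)
            pred = predict_pls(model, X[i][None, :])[0]
            press[a - 1] += (y[i] - pred) ** 2
    return press


class TestFitPredict:
    def test_full_rank_pls_equals_ols(self, random_problem):
        X, y = random_problem
        model = fit_pls(X, y, ncomp=10)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        ols_pred = Xc @ beta + y.mean()
        np.testing.assert_allclose(predict_pls(model, X), ols_pred, atol=1e-6)

    def test_single_proportional_column_exact_fit(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((15, 4))
        y = 3.5 * X[:, 2]
        model = fit_pls(X[:, [2]], y, ncomp=1)
        r2, _ = regression_metrics(y, predict_pls(model, X[:, [2]]))
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_first_weight_is_covariance_direction(self, random_problem):
        X, y = random_problem
        model = fit_pls(X, y, ncomp=1)
        Xc = X - X.mean(axis=0)
        w_expected = Xc.T @ (y - y.mean())
        w_expected /= np.linalg.norm(w_expected)
        np.testing.assert_allclose(np.abs(model.weights[:, 0]), np.abs(w_expected),
                                   atol=1e-10)

    def test_scores_orthogonal(self, random_problem):
        X, y = random_problem
        T = fit_pls(X, y, 5).scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.diag(gram).max()

    def test_predict_training_reproduces_fitted(self, random_problem):
        X, y = random_problem
        model = fit_pls(X, y, 3)
        fitted = model.scores @ model.y_loadings + model.y_mean
        np.testing.assert_allclose(predict_pls(model, X), fitted, atol=1e-9)

    def test_mean_row_predicts_mean_response(self, random_problem):
        X, y = random_problem
        model = fit_pls(X, y, 3)
        pred = predict_pls(model, X.mean(axis=0)[None, :])
        assert pred[0] == pytest.approx(y.mean())

    def test_translation_equivariance(self, random_problem):
        X, y = random_problem
        p1 = predict_pls(fit_pls(X, y, 3), X)
        p2 = predict_pls(fit_pls(X, y + 10.0, 3), X)
        np.testing.assert_allclose(p2, p1 + 10.0, atol=1e-9)

    def test_training_rmse_monotone_in_ncomp(self, random_problem):
        X, y = random_problem
        rmses = []
        for a in range(1, 9):
            model = fit_pls(X, y, a)
            _, rmse = regression_metrics(y, predict_pls(model, X))
            rmses.append(rmse)
        assert all(b <= a + 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_duplicated_channel_leaves_full_rank_predictions_stable(
        self, random_problem
    ):
        # at full rank PLS coincides with least squares on the column span,
        # which a duplicated channel does not change
        X, y = random_problem
        X_dup = np.hstack([X, X[:, [0]]])
        p1 = predict_pls(fit_pls(X, y, 10), X)
        p2 = predict_pls(fit_pls(X_dup, y, 10), X_dup)
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_matches_sklearn_nipals(self, random_problem):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_problem
        ours = predict_pls(fit_pls(X, y, 4), X)
        ref = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(ours, ref.predict(X).ravel(), atol=1e-8)

    def test_ncomp_capped_with_warning(self, random_problem):
        X, y = random_problem
        with pytest.warns(UserWarning, match="capped"):
            model = fit_pls(X, y, 50)
        assert model.ncomp <= 10

    def test_constant_response_rejected(self, random_problem):
        X, _ = random_problem
        with pytest.raises(DegenerateResponseError):
            fit_pls(X, np.ones(20), 2)

    def test_channel_mismatch_rejected(self, random_problem):
        X, y = random_problem
        model = fit_pls(X, y, 2)
        with pytest.raises(DomainError):
            predict_pls(model, X[:, :5])

    def test_json_round_trip(self, random_problem, tmp_path):
        X, y = random_problem
        model = fit_pls(X, y, 3, variable_indices=np.arange(10))
        path = tmp_path / "model.json"
        model.to_json(path)
        clone = PLSModel.from_json(path)
        np.testing.assert_allclose(predict_pls(clone, X), predict_pls(model, X))
        np.testing.assert_array_equal(clone.variable_indices, model.variable_indices)


class TestLoocv:
    def test_matches_brute_force_refits(self, random_problem):
        X, y = random_problem
        curve = loocv_curve(X, y, 5)
        np.testing.assert_allclose(curve.press, brute_force_loocv(X, y, 5),
                                   atol=1e-8)

    def test_three_sample_hand_computation(self):
        # X single channel, y noisy multiple; each LOO fit is a 2-point
        # 1-component PLS = straight line through the two training points
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 4.0])
        press_hand = 0.0
        for i in range(3):
            mask = np.arange(3) != i
            x_tr, y_tr = X[mask, 0], y[mask]
            slope = (y_tr[1] - y_tr[0]) / (x_tr[1] - x_tr[0])
            pred = y_tr[0] + slope * (X[i, 0] - x_tr[0])
            press_hand += (y[i] - pred) ** 2
        curve = loocv_curve(X, y, 1)
        assert curve.press[0] == pytest.approx(press_hand)
        assert curve.rmsecv[0] == pytest.approx(np.sqrt(press_hand / 3))

    def test_duplicating_samples_does_not_hurt_press(self, random_problem):
        X, y = random_problem
        c1 = loocv_curve(X, y, 3)
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        c2 = loocv_curve(X2, y2, 3)
        # with a twin present, each LOO prediction improves
        assert c2.rmsecv[-1] <= c1.rmsecv[-1] + 1e-9

    def test_invalid_max_comp_rejected(self, random_problem):
        X, y = random_problem
        with pytest.raises(DomainError):
            loocv_curve(X, y, 0)


class TestSelectNcomp:
    @pytest.mark.parametrize(
        "rmsecv, expected", [((3, 1, 2), 2), ((2, 1, 1), 2), ((5,), 1)]
    )
    def test_argmin_with_parsimony_ties(self, rmsecv, expected):
        k = len(rmsecv)
        curve = CVCurve(
            press=np.array(rmsecv, dtype=float) ** 2,
            rmsecv=np.array(rmsecv, dtype=float),
            r2_cv=1 - np.array(rmsecv, dtype=float),
            n_samples=10,
            max_components=k,
        )
        assert select_ncomp(curve) == expected


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert regression_metrics(y, y) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_null_model_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        r2, _ = regression_metrics(y, np.full(3, 2.0))
        assert r2 == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # SSE = (0-1)^2 + (2-1)^2 = 2; SST about mean(y)=1 is 2; R^2 = 0
        r2, rmse = regression_metrics(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        assert rmse == pytest.approx(1.0)
        assert r2 == pytest.approx(0.0)

    def test_constant_y_rejected(self):
        with pytest.raises(ZeroVarianceError):
            regression_metrics(np.ones(5), np.zeros(5))
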