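import numpy as np
import pandas as pd
import pytest

from qsarpls.dataset import ActivityVector
from qsarpls.descriptors import DescriptorMatrix
from qsarpls.regression import (
    RegressionModel,
    fit_mlr,
    fit_pls,
    predict,
    select_lv,
    stepwise_select,
)

from oracles import ols_normal_equations


def _xy(V, y):
    V = np.asarray(V, dtype=float)
    ids = [f"c{k}" for k in range(V.shape[0])]
    X = DescriptorMatrix(
        frame=pd.DataFrame(V, index=ids, columns=[f"d{j}" for j in range(V.shape[1])])
    )
    return X, ActivityVector(ids=ids, values=np.asarray(y, dtype=float))


class TestMLR:
    def test_noiseless_linear_system_fits_exactly(self, rng):
        V = rng.standard_normal((30, 3))
        y = V @ [1.0, -2.0, 0.5] + 4.0
        X, yv = _xy(V, y)
        m = fit_mlr(X, yv)
        assert m.stats["r2"] == pytest.approx(1.0)
        assert np.allclose(predict(m, X), y)

    def test_identity_single_column(self):
        X, yv = _xy([[1.0], [2.0], [3.0], [4.0]], [1.0, 2.0, 3.0, 4.0])
        m = fit_mlr(X, yv)
        assert m.coef[0] == pytest.approx(1.0) and m.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(50)
        V = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        X, yv = _xy(V, y)
        m = fit_mlr(X, yv)
        b0, b = ols_normal_equations(V, y)
        assert m.intercept == pytest.approx(b0, abs=1e-10)
        assert np.allclose(m.coef, b, atol=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        V = rng.standard_normal((20, 2))
        V = np.column_stack([V, V[:, 0]])
        X, yv = _xy(V, rng.standard_normal(20))
        with pytest.raises(ValueError, match="rank deficient"):
            fit_mlr(X, yv)

    def test_too_few_samples_rejected(self, rng):
        X, yv = _xy(rng.standard_normal((4, 4)), rng.standard_normal(4))
        with pytest.raises(ValueError, match="n > p"):
            fit_mlr(X, yv)


class TestStepwise:
    def test_planted_dominant_column_selected_first(self):
        rng = np.random.default_rng(7)
        V = rng.standard_normal((100, 21))
        y = 2.0 * V[:, 3] + rng.normal(0, 0.1, 100)
        X, yv = _xy(V, y)
        names, model, trace = stepwise_select(X, yv)
        assert names[0] == "d3"
        assert model is not None

    def test_pure_noise_with_tiny_alpha_selects_nothing(self):
        rng = np.random.default_rng(13)
        X, yv = _xy(rng.standard_normal((80, 10)), rng.standard_normal(80))
        names, model, trace = stepwise_select(X, yv, alpha_enter=1e-6, alpha_remove=1e-5)
        assert names == [] and model is None

    def test_alpha_one_enters_max_terms(self, rng):
        X, yv = _xy(rng.standard_normal((60, 8)), rng.standard_normal(60))
        names, model, _ = stepwise_select(X, yv, alpha_enter=1.0, alpha_remove=1.0, max_terms=4)
        assert len(names) == 4

    def test_alpha_ordering_enforced(self, rng):
        X, yv = _xy(rng.standard_normal((30, 3)), rng.standard_normal(30))
        with pytest.raises(ValueError, match="alpha_enter"):
            stepwise_select(X, yv, alpha_enter=0.2, alpha_remove=0.1)


class TestPLS:
    def test_full_rank_pls_equals_ols(self, rng):
        for _ in range(5):
            V = rng.standard_normal((40, 6))
            y = rng.standard_normal(40)
            X, yv = _xy(V, y)
            m_pls = fit_pls(X, yv, n_lv=6)
            b0, b = ols_normal_equations(V, y)
            assert np.allclose(predict(m_pls, X), V @ b + b0, atol=1e-8)

    def test_orthogonal_response_first_lv_explains_nothing(self):
        rng = np.random.default_rng(3)
        V = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        # orthogonalize y against all columns (and the intercept)
        M = np.column_stack([np.ones(50), V])
        y = y - M @ np.linalg.lstsq(M, y, rcond=None)[0]
        X, yv = _xy(V, y)
        m = fit_pls(X, yv, 1)
        ss_res = np.sum((predict(m, X) - y) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot == pytest.approx(0.0, abs=1e-6)

    def test_duplicated_columns_leave_predictions_unchanged(self, rng):
        V = rng.standard_normal((40, 4))
        y = V @ [1.0, 0.5, -1.0, 0.2] + rng.normal(0, 0.1, 40)
        X1, yv = _xy(V, y)
        X2, _ = _xy(np.column_stack([V, V]), y)
        p1 = predict(fit_pls(X1, yv, 2), X1)
        p2 = predict(fit_pls(X2, yv, 2), X2)
        assert np.allclose(p1, p2, atol=1e-8)

    def test_agrees_with_sklearn_pls(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        V = rng.standard_normal((60, 8))
        y = V @ rng.standard_normal(8) + rng.normal(0, 0.5, 60)
        X, yv = _xy(V, y)
        for n_lv in (1, 3, 5):
            ours = predict(fit_pls(X, yv, n_lv), X)
            ref = PLSRegression(n_components=n_lv, scale=True).fit(V, y).predict(V).ravel()
            assert np.allclose(ours, ref, atol=1e-8)

    def test_n_lv_beyond_rank_rejected(self, rng):
        V = rng.standard_normal((20, 3))
        X, yv = _xy(np.column_stack([V, V[:, 0]]), rng.standard_normal(20))
        with pytest.raises(ValueError, match="n_lv"):
            fit_pls(X, yv, 4)


class TestSelectLV:
    def test_recovers_three_latent_factors(self):
        rng = np.random.default_rng(99)
        n, p = 200, 20
        F = rng.standard_normal((n, 3))
        load = rng.standard_normal((3, p))
        V = F @ load  # exactly rank 3: the RMSECV curve is flat beyond 3 LVs
        y = F @ [2.0, -1.0, 1.5] + rng.normal(0, 0.05, n)
        X, yv = _xy(V, y)
        lv, curve = select_lv(X, yv, max_lv=8, cv=10)
        assert lv == 3
        assert len(curve) == 8

    def test_max_lv_one(self, rng):
        X, yv = _xy(rng.standard_normal((30, 5)), rng.standard_normal(30))
        lv, curve = select_lv(X, yv, max_lv=1, cv=5)
        assert lv == 1 and len(curve) == 1

    def test_folds_exceeding_samples_rejected(self, rng):
        X, yv = _xy(rng.standard_normal((10, 3)), rng.standard_normal(10))
        with pytest.raises(ValueError, match="folds"):
            select_lv(X, yv, max_lv=2, cv=11)


class TestPredictAndSerialize:
    def test_residual_convention_predicted_minus_experimental(self):
        # matches the published test-set table: 7.34 - 7.24 = 0.10
        assert round(7.34 - 7.24, 2) == 0.10
        X, yv = _xy([[0.0], [1.0], [2.0]], [1.0, 2.0, 3.0])
        m = fit_mlr(X, yv)
        resid = predict(m, X) - yv.values
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_all_zero_row_predicts_intercept(self, rng):
        V = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        X, yv = _xy(V, y)
        m = fit_mlr(X, yv)
        X0, _ = _xy(np.zeros((1, 3)), [0.0])
        assert predict(m, X0)[0] == pytest.approx(m.intercept)

    def test_missing_column_rejected(self, rng):
        X, yv = _xy(rng.standard_normal((20, 3)), rng.standard_normal(20))
        m = fit_mlr(X, yv)
        X2 = DescriptorMatrix(frame=X.frame[["d0", "d1"]])
        with pytest.raises(KeyError, match="d2"):
            predict(m, X2)

    def test_json_round_trip(self, rng):
        V = rng.standard_normal((25, 4))
        X, yv = _xy(V, rng.standard_normal(25))
        m = fit_pls(X, yv, 2)
        m2 = RegressionModel.from_json(m.to_json())
        assert m2.kind == "PLS" and m2.n_lv == 2 and m2.names == m.names
        assert np.allclose(predict(m2, X), predict(m, X))
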