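"""Linear activity model: OLS correctness, published-equation predictions,
fit statistics, contribution scores."""

import json

import numpy as np
import pandas as pd
import pytest

from oxaqsar import (
    MODEL_TERMS,
    LinearQSAR,
    published_mlr_model,
)


def _toy_design(seed=0, n=4, p=2):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 5, size=(n, p))
    y = rng.uniform(0, 10, size=n)
    return X, y


class TestOlsCore:
    def test_matches_normal_equations_oracle(self):
        # brute-force (X'X)^(-1) X'y on a 4-point, 2-descriptor toy set
        X, y = _toy_design()
        A = np.column_stack([np.ones(len(X)), X])
        beta_oracle = np.linalg.inv(A.T @ A) @ A.T @ y
        model = LinearQSAR(terms=["a", "b"]).fit(X, y)
        assert model.intercept_ == pytest.approx(beta_oracle[0], rel=1e-10)
        assert model.coef_ == pytest.approx(beta_oracle[1:], rel=1e-10)

    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(0, 1, 6).reshape(-1, 1)
        model = LinearQSAR(terms=["x"]).fit(x, 2 + 3 * x.ravel())
        assert model.intercept_ == pytest.approx(2.0, abs=1e-10)
        assert model.coef_[0] == pytest.approx(3.0, abs=1e-10)
        assert model.stats_.r2 == pytest.approx(1.0, abs=1e-12)

    def test_residuals_orthogonal_to_design(self, training, mlr_refit):
        Xd = training[MODEL_TERMS].to_numpy()
        resid = training["pIC50_obs"].to_numpy() - mlr_refit.predict(training)
        A = np.column_stack([np.ones(len(Xd)), Xd])
        scale = np.abs(A).sum(axis=0) * np.abs(resid).max()
        assert np.all(np.abs(A.T @ resid) <= 1e-8 * np.maximum(scale, 1.0))

    def test_agrees_with_statsmodels(self, training, mlr_refit):
        sm = pytest.importorskip("statsmodels.api")
        X = sm.add_constant(training[MODEL_TERMS].to_numpy())
        fit = sm.OLS(training["pIC50_obs"].to_numpy(), X).fit()
        assert mlr_refit.intercept_ == pytest.approx(fit.params[0], rel=1e-8)
        assert mlr_refit.coef_ == pytest.approx(fit.params[1:], rel=1e-8)
        assert mlr_refit.stats_.r2 == pytest.approx(fit.rsquared, abs=1e-10)
        assert mlr_refit.stats_.f_statistic == pytest.approx(fit.fvalue, rel=1e-8)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            LinearQSAR(terms=["a", "b"]).fit(X, np.arange(6.0))

    def test_too_few_records_rejected(self, training):
        with pytest.raises(ValueError, match="at least"):
            LinearQSAR().fit(training.head(6), training["pIC50_obs"].head(6))


class TestStudyRefit:
    def test_fit_statistics_match_reported(self, mlr_refit):
        s = mlr_refit.stats_
        assert (s.n, s.p) == (25, 6)
        assert s.r2 == pytest.approx(0.91, abs=0.01)
        assert s.f_statistic == pytest.approx(30.36, abs=0.5)
        assert s.mse == pytest.approx(0.020, abs=0.002)
        assert s.r2_adjusted == pytest.approx(0.88, abs=0.01)
        assert s.p_value < 1e-4

    def test_f_consistent_with_r2(self, mlr_refit):
        s = mlr_refit.stats_
        assert s.f_statistic == pytest.approx(
            (s.r2 / s.p) / ((1 - s.r2) / (s.n - s.p - 1)), abs=1e-6)

    def test_training_predictions_match_reference_table(self, dataset, training, mlr_refit):
        ref = dataset.published_predictions.set_index("compound_id")
        pred = mlr_refit.predict(training)
        expected = ref.loc[training["compound_id"], "mlr_pred"].to_numpy()
        assert np.abs(pred - expected).max() < 0.05


class TestPublishedEquation:
    def test_candidate_predictions_reproduce_reported_values(self, dataset):
        model = published_mlr_model()
        pred = np.round(model.predict(dataset.candidates), 2)
        assert pred.tolist() == [9.28, 9.53, 9.38, 9.42, 9.58]

    def test_zero_descriptor_vector_gives_intercept(self):
        model = published_mlr_model()
        assert model.predict(np.zeros((1, 6)))[0] == pytest.approx(-10.59993)

    def test_published_and_refit_are_close_but_distinct(self, mlr_refit):
        pub = published_mlr_model()
        assert pub.coef_ == pytest.approx(mlr_refit.coef_, rel=0.05)
        assert not np.array_equal(pub.coef_, mlr_refit.coef_)


class TestContributions:
    def test_signs_match_reported_direction(self, training, mlr_refit):
        # favorable: S, MP, eta; unfavorable: Tor, NRB, repul
        scores = dict(zip(MODEL_TERMS, mlr_refit.standardized_coefficients(training)))
        assert scores["S"] > 0 and scores["MP"] > 0 and scores["eta"] > 0
        assert scores["Tor"] < 0 and scores["NRB"] < 0 and scores["repul"] < 0

    def test_scores_equal_coef_times_sd_oracle(self):
        X = np.array([[1.0, 10.0], [2.0, 30.0], [3.0, 20.0], [4.0, 40.0]])
        y = np.array([1.0, 2.0, 2.5, 4.0])
        model = LinearQSAR(terms=["a", "b"]).fit(X, y)
        sd = X.std(axis=0, ddof=1)
        assert model.standardized_coefficients(X) == pytest.approx(model.coef_ * sd)

    def test_zero_coefficients_give_zero_scores(self):
        model = LinearQSAR.from_coefficients(1.0, [0.0, 0.0], terms=["a", "b"])
        X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert model.standardized_coefficients(X) == pytest.approx([0.0, 0.0])

    def test_zero_variance_descriptor_rejected(self):
        model = LinearQSAR.from_coefficients(0.0, [1.0, 1.0], terms=["a", "b"])
        X = np.array([[1.0, 2.0], [1.0, 4.0], [1.0, 6.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            model.standardized_coefficients(X)


class TestInterface:
    def test_missing_descriptor_column_rejected(self, mlr_refit):
        with pytest.raises(ValueError, match="missing descriptor"):
            mlr_refit.predict(pd.DataFrame({"S": [3.0]}))

    def test_json_round_trip(self, mlr_refit):
        restored = LinearQSAR.from_json(mlr_refit.to_json())
        assert restored.intercept_ == mlr_refit.intercept_
        assert restored.coef_ == pytest.approx(mlr_refit.coef_, rel=0, abs=0)
        assert restored.stats_ == mlr_refit.stats_
        payload = json.loads(mlr_refit.to_json())
        assert payload["terms"] == MODEL_TERMS
        assert len(payload["fitted_on"]) == 25

    def test_sklearn_params_round_trip(self):
        model = LinearQSAR(terms=["a", "b"])
        assert LinearQSAR(**model.get_params()).terms == ["a", "b"]
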