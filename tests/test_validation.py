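"""Cross-validation and the external-validation battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxaqsar import LinearQSAR, golbraikh_tropsha, loo_q2, mse, rmse


def _univariate(n=5, seed=2):
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 4, n)
    y = 1.0 + 0.8 * x + rng.normal(0, 0.3, n)
    return pd.DataFrame({"compound_id": [str(i) for i in range(n)],
                         "x": x, "pIC50_obs": y})


class TestLooQ2:
    def test_matches_exhaustive_normal_equations_oracle(self):
        df = _univariate()
        x, y = df["x"].to_numpy(), df["pIC50_obs"].to_numpy()
        preds = []
        for i in range(len(df)):  # hand-rolled LOO: 5 independent 2x2 solves
            m = np.ones(len(df), bool); m[i] = False
            A = np.column_stack([np.ones(m.sum()), x[m]])
            beta = np.linalg.solve(A.T @ A, A.T @ y[m])
            preds.append(beta[0] + beta[1] * x[i])
        press = np.sum((y - np.array(preds)) ** 2)
        q2_oracle = 1 - press / np.sum((y - y.mean()) ** 2)
        report = loo_q2(df, LinearQSAR(terms=["x"]))
        assert report.q2 == pytest.approx(q2_oracle, rel=1e-10)
        assert report.predictions["predicted"].to_numpy() == pytest.approx(np.array(preds))

    def test_oracle_model_on_noiseless_data_gives_q2_one(self):
        class TrueModel:
            def get_params(self, deep=True):
                return {}

            def set_params(self, **kw):
                return self

            def fit(self, X, y):
                return self

            def predict(self, X):
                return 1.0 + 2.0 * X["x"].to_numpy()

        x = np.linspace(0, 3, 6)
        df = pd.DataFrame({"x": x, "pIC50_obs": 1.0 + 2.0 * x})
        assert loo_q2(df, TrueModel()).q2 == pytest.approx(1.0)

    def test_study_training_set_reproduces_reported_q2(self, training):
        report = loo_q2(training)
        assert report.q2 == pytest.approx(0.83, abs=0.02)
        assert report.mse_cv == pytest.approx(0.027, abs=0.005)
        assert len(report.predictions) == 25
        assert report.predictions["compound_id"].is_unique

    def test_q2_below_training_r2(self, training, mlr_refit):
        assert loo_q2(training).q2 < mlr_refit.stats_.r2

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            loo_q2(_univariate(n=2))


class TestGolbraikhTropsha:
    def test_study_test_set_reproduces_reported_battery(self, dataset):
        rep = golbraikh_tropsha(dataset.test_pairs["pIC50_obs"],
                                dataset.test_pairs["pIC50_pred_mlr"])
        assert round(rep.r2, 4) == 0.7049
        assert round(rep.r0_sq, 4) == 0.6922
        assert round(rep.r0p_sq, 3) == 0.661
        assert round(rep.k_prime, 2) == 0.99
        assert round(rep.ratio1, 3) == 0.018
        assert round(rep.ratio2, 3) == 0.062
        assert rep.all_pass

    def test_slope_convention_lock(self, dataset):
        # predicted-on-observed through-origin slope ~1.006 (prints as 1.00
        # under truncation); the converse slope rounds to 0.99
        rep = golbraikh_tropsha(dataset.test_pairs["pIC50_obs"],
                                dataset.test_pairs["pIC50_pred_mlr"])
        assert rep.k == pytest.approx(1.0065, abs=5e-4)
        assert int(rep.k * 100) / 100 == 1.00  # truncates to the printed K
        assert round(rep.k_prime, 2) == 0.99

    def test_identical_pairs_give_perfect_metrics(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rep = golbraikh_tropsha(y, y)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.r0_sq == pytest.approx(1.0)
        assert rep.r0p_sq == pytest.approx(1.0)
        assert rep.k == pytest.approx(1.0) and rep.k_prime == pytest.approx(1.0)
        assert rep.delta_r0 == pytest.approx(0.0)
        assert rep.all_pass

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metrics_match_raw_sum_rederivation(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(5, 9, 10)
        yhat = y + rng.normal(0, 0.5, 10)
        rep = golbraikh_tropsha(y, yhat)
        # independent re-derivation from the defining sums
        syy, shh, syh = (y * y).sum(), (yhat * yhat).sum(), (y * yhat).sum()
        k, kp = syh / syy, syh / shh
        r0 = 1 - ((yhat - k * y) ** 2).sum() / ((yhat - yhat.mean()) ** 2).sum()
        r0p = 1 - ((y - kp * yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        sxy = ((y - y.mean()) * (yhat - yhat.mean())).sum()
        r2 = sxy ** 2 / (((y - y.mean()) ** 2).sum() * ((yhat - yhat.mean()) ** 2).sum())
        assert rep.k == pytest.approx(k, rel=1e-12)
        assert rep.k_prime == pytest.approx(kp, rel=1e-12)
        assert rep.r0_sq == pytest.approx(r0, rel=1e-12)
        assert rep.r0p_sq == pytest.approx(r0p, rel=1e-12)
        assert rep.r2 == pytest.approx(r2, rel=1e-9)
        # internal consistency of the stored ratios and delta
        assert rep.ratio1 == (rep.r2 - rep.r0_sq) / rep.r2
        assert rep.ratio2 == (rep.r2 - rep.r0p_sq) / rep.r2
        assert rep.delta_r0 == abs(rep.r0_sq - rep.r0p_sq)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            golbraikh_tropsha([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="at least 3"):
            golbraikh_tropsha([1.0, 2.0], [1.0, 2.0])


class TestErrorMetrics:
    def test_perfect_pairs_have_zero_rmse(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_reported_training_mse_from_reference_residuals(self, dataset):
        resid = dataset.published_predictions.set_index("compound_id")
        train_ids = dataset.training()["compound_id"]
        r = resid.loc[train_ids, "mlr_resid"].to_numpy()
        assert mse(r, np.zeros_like(r), dof=18) == pytest.approx(0.020, abs=0.001)

    def test_hand_picked_pairs(self):
        # ((1-2)^2 + (3-5)^2 + (4-3)^2) / 3 = 2
        assert mse([1, 3, 4], [2, 5, 3]) == pytest.approx(2.0)
        assert rmse([1, 3, 4], [2, 5, 3]) == pytest.approx(np.sqrt(2.0))

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            mse([], [])
        with pytest.raises(ValueError):
            mse([1.0], [1.0], dof=0)
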