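import numpy as np
import pandas as pd
import pytest

from ldjump.regression import (
    RateEstimate,
    TrainedModel,
    apply_bias_correction,
    boxcox,
    fit_bias_correction,
    fit_gam,
    inverse_boxcox,
    predict_rho,
    predict_table,
    term_f_tests,
)
from ldjump.stats import PREDICTORS, SummaryVector


def synthetic_table(n_rows=800, lmbda=0.5, noise=0.0, seed=0):
    """Training table whose transformed response is an exact additive cubic
    function of the predictors (cubic polynomials lie inside the spline
    space, so a near-unpenalized fit can recover them exactly)."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n_rows, len(PREDICTORS)))
    coef = np.linspace(-0.6, 0.6, len(PREDICTORS))
    t = sum(
        c * (x**3 - 0.4 * x) for c, x in zip(coef, X.T)
    ) + 0.2 * rng.standard_normal(n_rows) * noise
    t = t - t.max() - 0.1  # keep the back-transform in (0, 1)
    rho = inverse_boxcox(t, lmbda)
    table = pd.DataFrame(X, columns=list(PREDICTORS))
    table["rho"] = rho
    return table


class TestBoxCox:
    def test_lambda_one_is_shift(self):
        assert boxcox(0.3, 1.0) == pytest.approx(-0.7)
        assert inverse_boxcox(-0.7, 1.0) == pytest.approx(0.3)

    def test_hand_value(self):
        assert boxcox(0.04, 0.5) == pytest.approx(-1.6)

    def test_log_limit(self):
        assert boxcox(np.e, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("lmbda", [0.0, 0.25, 0.5, 1.0])
    def test_round_trip(self, lmbda):
        rho = np.linspace(1e-4, 0.1, 50)
        assert np.allclose(inverse_boxcox(boxcox(rho, lmbda), lmbda), rho,
                           atol=1e-12)

    def test_forward_requires_positive(self):
        with pytest.raises(ValueError):
            boxcox(0.0, 0.5)

    def test_inverse_clamps_below_domain(self):
        assert inverse_boxcox(-10.0, 0.5) == 0.0


class TestFitGam:
    def test_noiseless_recovery(self):
        table = synthetic_table(noise=0.0)
        model = fit_gam(table, lambda_policy=0.5, penalty=1e-9)
        t_hat, _ = predict_table(model, table)
        t_true = boxcox(table["rho"].to_numpy(), 0.5)
        assert np.allclose(t_hat, t_true, atol=1e-6)

    def test_profile_lambda_recovers_generating_exponent(self):
        table = synthetic_table(noise=1.0, lmbda=0.5, seed=3)
        model = fit_gam(table, lambda_policy="profile")
        assert 0.2 <= model.lmbda <= 0.8

    def test_missing_column_rejected(self):
        table = synthetic_table().drop(columns=["nss"])
        with pytest.raises(ValueError, match="nss"):
            fit_gam(table)

    def test_constant_predictor_named_in_error(self):
        table = synthetic_table()
        table["maxchi"] = 1.0
        with pytest.raises(ValueError, match="maxchi"):
            fit_gam(table)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_gam(synthetic_table(n_rows=20))

    def test_agrees_with_statsmodels_gam(self):
        """Independent cross-check: statsmodels' penalized B-spline GAM on
        the same data produces essentially the same fitted surface."""
        from statsmodels.gam.api import BSplines, GLMGam

        table = synthetic_table(noise=0.1, seed=9)
        model = fit_gam(table, lambda_policy=0.5)
        t_hat, _ = predict_table(model, table)
        X = table[list(PREDICTORS)].to_numpy()
        y = boxcox(table["rho"].to_numpy(), 0.5)
        smoother = BSplines(X, df=[8] * X.shape[1], degree=[3] * X.shape[1])
        res = GLMGam(y, np.ones((len(y), 1)), smoother=smoother,
                     alpha=[0.0] * X.shape[1]).fit()
        assert np.corrcoef(t_hat, res.fittedvalues)[0, 1] > 0.999


@pytest.fixture(scope="module")
def model():
    return fit_gam(synthetic_table(noise=0.2, seed=4), lambda_policy=0.5)


@pytest.fixture(scope="module")
def model_and_calib():
    model = fit_gam(synthetic_table(noise=0.0, seed=5), lambda_policy=0.5,
                    penalty=1e-9)
    # calibration rows: true rho scattered symmetrically (on the transformed
    # scale) around the model's own prediction
    rng = np.random.default_rng(6)
    calib = synthetic_table(n_rows=10_000, noise=0.0, seed=7)
    t_hat, _ = predict_table(model, calib)
    calib["rho"] = inverse_boxcox(t_hat + 0.15 * rng.standard_normal(len(calib)), 0.5)
    calib = calib[calib["rho"] > 0]
    fit_bias_correction(model, calib)
    return model, calib


class TestPrediction:
    def sv(self, values):
        kw = dict(zip(PREDICTORS, values))
        return SummaryVector(
            tajd=float("nan"), snp_count=10, imputed=False, **kw
        )

    def test_training_row_reproduced(self, model):
        table = synthetic_table(noise=0.2, seed=4)
        t_hat, rho_hat = predict_table(model, table)
        est = predict_rho(model, self.sv(table.iloc[0, :7].to_numpy()))
        assert est.t_raw == pytest.approx(t_hat[0], abs=1e-12)
        assert est.rho_hat_raw == pytest.approx(rho_hat[0], abs=1e-12)

    def test_prediction_never_negative(self, model):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(
            rng.uniform(0, 1, size=(10_000, 7)), columns=list(PREDICTORS)
        )
        _, rho = predict_table(model, table)
        assert np.all(rho >= 0.0)

    def test_out_of_hull_clamped_to_boundary(self, model):
        inside = self.sv(np.full(7, 0.5))
        far = self.sv(np.array([0.5, 0.5, 0.5, 99.0, 0.5, 0.5, 0.5]))
        edge = self.sv(np.array([0.5, 0.5, 0.5, 1.0, 0.5, 0.5, 0.5]))
        far_edge = predict_rho(model, far)
        assert far_edge.t_raw == pytest.approx(
            predict_rho(model, edge).t_raw, rel=1e-6
        )
        assert far_edge.t_raw != predict_rho(model, inside).t_raw

    def test_flagged_segment_rejected(self, model):
        sv = SummaryVector(
            haps=0.001, vapw=0, apwd=0, wath=0, hahe=float("nan"),
            maxchi=float("nan"), nss=float("nan"), tajd=float("nan"),
            snp_count=0, imputed=True,
        )
        with pytest.raises(ValueError):
            predict_rho(model, sv)

    def test_serialization_round_trip_bit_exact(self, model, tmp_path):
        path = tmp_path / "model.json"
        model.save(path)
        clone = TrainedModel.load(path)
        table = synthetic_table(noise=0.2, seed=12)
        t_a, r_a = predict_table(model, table)
        t_b, r_b = predict_table(clone, table)
        assert np.array_equal(t_a, t_b) and np.array_equal(r_a, r_b)
        assert clone.lmbda == model.lmbda
        assert clone.bias_correction == model.bias_correction

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="format"):
            TrainedModel.from_json('{"format": "something-else"}')


class TestBiasCorrection:
    def test_median_quantile_near_identity_for_unbiased_estimator(
        self, model_and_calib
    ):
        model, _ = model_and_calib
        a, b = model.bias_correction[0.5]
        assert a == pytest.approx(0.0, abs=0.05)
        assert b == pytest.approx(1.0, abs=0.05)

    def test_all_slopes_positive(self, model_and_calib):
        model, _ = model_and_calib
        assert all(b > 0 for _, b in model.bias_correction.values())

    def test_correction_monotone_in_raw_estimate(self, model_and_calib):
        model, _ = model_and_calib
        t_vals = np.linspace(-1.8, -0.3, 25)
        for q in (0.25, 0.35, 0.45, 0.5):
            out = [
                apply_bias_correction(
                    model, RateEstimate(0, 0, t, False), q=q
                ).rho_hat
                for t in t_vals
            ]
            assert np.all(np.diff(out) >= 0)

    def test_identity_coefficients_leave_estimate_unchanged(self):
        model = fit_gam(synthetic_table(seed=10), lambda_policy=0.5)
        model.bias_correction[0.35] = (0.0, 1.0)
        est = RateEstimate(rho_hat=0.0, rho_hat_raw=0.04, t_raw=boxcox(0.04, 0.5))
        out = apply_bias_correction(model, est, q=0.35)
        assert out.rho_hat == pytest.approx(0.04, abs=1e-12)

    def test_unknown_quantile_lists_available(self, model_and_calib):
        model, _ = model_and_calib
        with pytest.raises(ValueError, match="0.25"):
            apply_bias_correction(model, RateEstimate(0, 0, -1.0), q=0.99)


def test_term_f_tests_detect_irrelevant_predictor():
    table = synthetic_table(noise=1.0, seed=11)
    rng = np.random.default_rng(12)
    table["haps"] = rng.uniform(0, 1, len(table))  # decouple one predictor
    model = fit_gam(table, lambda_policy=0.5)
    pvals = term_f_tests(table, model)
    assert pvals["haps"] > 0.01
    assert min(p for k, p in pvals.items() if k != "haps") < 1e-6
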