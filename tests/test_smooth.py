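"""Penalized exposure-response fitting: GLM limits, smoothing, prediction."""

import numpy as np
import pandas as pd
import pytest

from heatattr.basis import SplineBasis
from heatattr.smooth import (
    SmoothFit,
    build_design,
    build_spline_basis,
    compare_models,
    fit_smooth,
    predict_rate,
)


def irls_glm(y, X, family, max_iter=100):
    """Textbook unpenalized IRLS for log-link GLMs (independent oracle)."""
    mu = y + 0.5 if family == "poisson" else y.copy()
    eta = np.log(mu)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        w = mu if family == "poisson" else np.ones_like(mu)
        z = eta + (y - mu) / mu
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
        eta = X @ beta
        mu = np.exp(eta)
    return beta


@pytest.fixture(scope="module")
def glm_data():
    rng = np.random.default_rng(10)
    x = rng.uniform(20, 38, 500)
    mu = np.exp(-1.2 + 0.1 * x)
    return x, rng.gamma(6.0, mu / 6.0), rng.poisson(mu * 5)


@pytest.mark.parametrize("family", ["gamma", "poisson"])
def test_unpenalized_linear_fit_matches_irls_oracle(glm_data, family):
    """With lam=0 and a straight-line term the fit is an ordinary GLM."""
    x, y_gamma, y_pois = glm_data
    y = y_gamma if family == "gamma" else y_pois.astype(float)
    design = build_design(x, linear=True)
    fit = fit_smooth(y, design, family=family, lam_grid=[0.0])
    X = np.column_stack([np.ones_like(x), x])
    oracle = irls_glm(y, X, family)
    # translate the centered parameterisation back to (intercept, slope)
    ours = np.array([fit.coef[0] - fit.coef[1] * x.mean(), fit.coef[1]])
    np.testing.assert_allclose(ours, oracle, atol=1e-6)


def test_nbasis_cap_enforced():
    x = np.linspace(0, 10, 50)
    with pytest.raises(ValueError, match="cap"):
        build_spline_basis(x, 6)
    with pytest.raises(ValueError):
        build_spline_basis(x, 2)


def test_exact_reconstruction_within_span():
    """A curve inside the spline span is reproduced exactly (no noise)."""
    x = np.linspace(20, 40, 200)
    basis, _ = build_spline_basis(x, 4)
    target = basis.design(x)[0] @ np.array([0.1, 0.5, -0.2, 0.8])
    design = build_design(x, n_basis=4)
    fit = fit_smooth(np.exp(target), design, family="gamma", lam_grid=[0.0])
    np.testing.assert_allclose(np.log(fit.fitted), target, atol=1e-8)


def test_infinite_smoothing_collapses_to_penalty_null_space():
    """Huge lam leaves only intercept + linear trend (edf near 2)."""
    rng = np.random.default_rng(4)
    x = rng.uniform(20, 38, 400)
    y = rng.gamma(4.0, np.exp(0.05 * x) / 4.0)
    design = build_design(x, n_basis=5)
    fit = fit_smooth(y, design, family="gamma", lam_grid=[1e12])
    assert fit.edf == pytest.approx(2.0, abs=0.05)


def test_gcv_selection_is_deterministic(records, rates):
    d1 = build_design(records["tmax"].to_numpy(), n_basis=4)
    d2 = build_design(records["tmax"].to_numpy(), n_basis=4)
    f1 = fit_smooth(rates, d1, family="gamma")
    f2 = fit_smooth(rates, d2, family="gamma")
    assert f1.lam == f2.lam
    np.testing.assert_array_equal(f1.coef, f2.coef)


class TestPredictRate:
    def test_training_data_reproduces_fitted_values(self, records, rates, gamma_fit):
        pred = predict_rate(
            gamma_fit,
            records["tmax"].to_numpy(),
            records[["dow", "month", "year"]],
        )
        np.testing.assert_allclose(pred, gamma_fit.fitted, rtol=1e-12)

    def test_cooler_series_predicts_lower_in_increasing_region(self, reduced_fit, records):
        x = np.linspace(30, 36, 20)  # increasing part of the risk curve
        hi = predict_rate(reduced_fit, x)
        lo = predict_rate(reduced_fit, x - 1.5)
        assert np.all(lo < hi)

    def test_extrapolation_warns_with_count(self, reduced_fit):
        with pytest.warns(UserWarning, match="2 point"):
            predict_rate(reduced_fit, np.array([50.0, 51.0, 30.0]))

    def test_covariate_contract_enforced(self, gamma_fit, reduced_fit):
        with pytest.raises(ValueError, match="supply"):
            predict_rate(gamma_fit, np.array([30.0]))
        with pytest.raises(ValueError, match="no covariates"):
            predict_rate(reduced_fit, np.array([30.0]), pd.DataFrame({"dow": ["Mon"]}))

    def test_unseen_level_maps_to_reference_with_warning(self, gamma_fit):
        cov = pd.DataFrame({"dow": ["Mon"], "month": ["Jun"], "year": ["1999"]})
        ref = pd.DataFrame(
            {"dow": ["Mon"], "month": ["Jun"], "year": [gamma_fit.covariate_levels["year"][0]]}
        )
        with pytest.warns(UserWarning, match="unseen"):
            p = predict_rate(gamma_fit, np.array([30.0]), cov)
        np.testing.assert_allclose(p, predict_rate(gamma_fit, np.array([30.0]), ref))


def test_gamma_rejects_nonpositive_response_with_labels():
    x = np.linspace(20, 30, 10)
    y = np.ones(10)
    y[3] = 0.0
    dates = pd.date_range("2015-06-01", periods=10).date
    with pytest.raises(ValueError, match="2015-06-04"):
        fit_smooth(y, build_design(x, n_basis=3), family="gamma", index=dates)


def test_serialization_round_trip(gamma_fit, records):
    back = SmoothFit.from_json(gamma_fit.to_json())
    cov = records[["dow", "month", "year"]].iloc[:50]
    x = records["tmax"].to_numpy()[:50]
    np.testing.assert_allclose(
        predict_rate(back, x, cov), predict_rate(gamma_fit, x, cov), rtol=1e-12
    )


class TestCompareModels:
    def test_ties_keep_input_order_and_schema(self, records, rates):
        d = build_design(records["tmax"].to_numpy(), n_basis=3)
        f = fit_smooth(rates, d, family="gamma")
        table = compare_models({"tmax": f, "tmax_again": f})
        assert list(table.columns) == ["metric", "aic", "dev_expl", "edf"]
        assert table["metric"].tolist() == ["tmax", "tmax_again"]
        assert table["aic"].iloc[0] == table["aic"].iloc[1]

    def test_noise_predictor_ranks_no_better(self, records, rates):
        rng = np.random.default_rng(12)
        x = records["tmax"].to_numpy()
        noise = rng.permutation(x)  # same marginal, no association
        f_sig = fit_smooth(rates, build_design(x, n_basis=3), family="gamma")
        f_noise = fit_smooth(rates, build_design(noise, n_basis=3), family="gamma")
        table = compare_models({"signal": f_sig, "shuffled": f_noise})
        assert table["metric"].iloc[0] == "signal"

    def test_mixed_responses_rejected(self, records, rates):
        x = records["tmax"].to_numpy()
        f1 = fit_smooth(rates, build_design(x, n_basis=3), family="gamma")
        f2 = fit_smooth(rates[:200], build_design(x[:200], n_basis=3), family="gamma")
        with pytest.raises(ValueError, match="same response"):
            compare_models({"a": f1, "b": f2})
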