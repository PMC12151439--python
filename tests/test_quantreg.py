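"""Quantile-parameterized distribution and the quantile regression model."""

import subprocess
import sys
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nbuw.distribution import nbuw_cdf, nbuw_pdf, nbuw_ppf
from nbuw.quantreg import (
    NBUWQuantileRegressor,
    ReparamParams,
    _design,
    link_mu,
    mu_to_alpha,
    regression_loglik,
    reparam_cdf,
    reparam_logpdf,
    reparam_pdf,
    reparam_ppf,
    simulate_regression_data,
)


def test_alpha_map_positive():
    rp = ReparamParams(beta=2.0, mu=0.3, q=0.5)
    assert rp.alpha > 0
    assert mu_to_alpha(0.5, 1.0, 0.5) == pytest.approx(np.log(2), rel=1e-12)


def test_reparam_matches_base_parameterization():
    """The two parameterizations are one density under the alpha map."""
    beta, mu, q = 2.0, 0.3, 0.5
    alpha = mu_to_alpha(mu, beta, q)
    y = np.linspace(0.05, 0.95, 19)
    np.testing.assert_allclose(
        reparam_pdf(y, beta, mu, q), nbuw_pdf(y, alpha, beta), rtol=1e-14
    )
    np.testing.assert_allclose(
        reparam_cdf(y, beta, mu, q), nbuw_cdf(y, alpha, beta), rtol=1e-14
    )
    assert reparam_ppf(0.25, beta, mu, q) == pytest.approx(
        nbuw_ppf(0.25, alpha, beta), abs=1e-12
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    beta=st.floats(0.2, 10.0),
    mu=st.floats(0.05, 0.95),
    q=st.floats(0.05, 0.95),
)
def test_quantile_anchoring_exact(beta, mu, q):
    """G(mu; beta, mu, q) == q: mu is the q-th quantile by construction."""
    assert reparam_cdf(mu, beta, mu, q) == pytest.approx(q, abs=1e-12)


def test_reparam_quantile_anchoring_and_inverse():
    beta, mu, q = 2.0, 0.3, 0.5
    assert reparam_ppf(q, beta, mu, q) == pytest.approx(mu, abs=1e-12)
    for u in (0.05, 0.5, 0.95):
        assert reparam_cdf(
            reparam_ppf(u, beta, mu, q), beta, mu, q
        ) == pytest.approx(u, abs=1e-10)
    assert reparam_cdf(1.0, beta, mu, q) == 1.0


def test_reparam_pdf_normalizes():
    from scipy import integrate

    total, _ = integrate.quad(
        lambda y: reparam_pdf(y, 2.0, 0.3, 0.5), 0, 1, limit=200
    )
    assert total == pytest.approx(1.0, abs=1e-8)


def test_link_is_stable_logistic():
    assert link_mu(0.0) == 0.5
    assert link_mu(40.0) == pytest.approx(1.0, abs=1e-15)
    assert link_mu(-40.0) == pytest.approx(0.0, abs=1e-15)
    mu = 0.37
    assert link_mu(np.log(mu / (1 - mu))) == pytest.approx(mu, abs=1e-12)


def test_regression_loglik_is_sum_of_logpdf(rng):
    X, y = simulate_regression_data((0.7, 0.4), 3.0, 0.5, 200, seed=5)
    design = _design(X)
    delta = np.array([0.6, 0.5])
    beta = 2.5
    ll = regression_loglik(beta, delta, design, y, 0.5)
    mu = link_mu(design @ delta)
    assert ll == pytest.approx(
        np.sum(reparam_logpdf(y, beta, mu, 0.5)), abs=1e-10
    )


def test_intercept_only_reduces_to_distribution_loglik():
    _, y = simulate_regression_data((0.4,), 2.0, 0.5, 150, seed=8)
    design = np.ones((y.size, 1))
    delta = np.array([0.4])
    ll = regression_loglik(2.0, delta, design, y, 0.5)
    mu = link_mu(0.4)
    assert ll == pytest.approx(
        np.sum(reparam_logpdf(y, 2.0, mu, 0.5)), abs=1e-10
    )


def test_loglik_peaks_at_mle():
    X, y = simulate_regression_data((1.3, 1.4), 2.0, 0.5, 400, seed=9)
    model = NBUWQuantileRegressor(q=0.5).fit(X, y)
    design = _design(X)
    delta_hat = np.array([model.intercept_, *model.coef_])
    ll_hat = regression_loglik(model.shape_, delta_hat, design, y, 0.5)
    for shift in ([0.05, 0.0], [0.0, -0.05]):
        ll = regression_loglik(
            model.shape_, delta_hat + np.array(shift), design, y, 0.5
        )
        assert ll < ll_hat


def test_simulated_data_support_and_determinism():
    X1, y1 = simulate_regression_data((1.3, 1.4), 2.0, 0.5, 500, seed=3)
    X2, y2 = simulate_regression_data((1.3, 1.4), 2.0, 0.5, 500, seed=3)
    np.testing.assert_array_equal(y1, y2)
    np.testing.assert_array_equal(X1, X2)
    assert np.all((y1 > 0) & (y1 < 1))


def test_simulated_quantile_coverage():
    X, y = simulate_regression_data((1.3, 1.4), 2.0, 0.5, 100_000, seed=4)
    mu = link_mu(1.3 + 1.4 * X[:, 0])
    assert np.mean(y < mu) == pytest.approx(0.5, abs=0.01)
    X, y = simulate_regression_data((-2.0, 1.0), 1.5, 0.1, 100_000, seed=5)
    mu = link_mu(-2.0 + 1.0 * X[:, 0])
    assert np.mean(y < mu) == pytest.approx(0.1, abs=0.01)


def test_fit_recovers_truth_large_n():
    X, y = simulate_regression_data((1.3, 1.4), 2.0, 0.5, 100_000, seed=7)
    model = NBUWQuantileRegressor(q=0.5).fit(X, y)
    assert model.converged_
    assert model.intercept_ == pytest.approx(1.3, abs=0.05)
    assert model.coef_[0] == pytest.approx(1.4, abs=0.05)
    assert model.shape_ == pytest.approx(2.0, abs=0.06)
    # fitted-quantile coverage on the training data
    assert np.mean(y < model.fitted_quantiles_) == pytest.approx(0.5,
                                                                 abs=0.02)


def test_permutation_invariance():
    X, y = simulate_regression_data((0.7, 0.4), 3.0, 0.5, 300, seed=11)
    rng = np.random.default_rng(0)
    perm = rng.permutation(y.size)
    m1 = NBUWQuantileRegressor().fit(X, y)
    m2 = NBUWQuantileRegressor().fit(X[perm], y[perm])
    assert m1.intercept_ == pytest.approx(m2.intercept_, abs=1e-6)
    assert m1.shape_ == pytest.approx(m2.shape_, abs=1e-6)


def test_information_criteria_fields():
    X, y = simulate_regression_data((1.0, 2.0), 4.0, 0.9, 200, seed=13)
    model = NBUWQuantileRegressor(q=0.9).fit(X, y)
    k = 3  # intercept + slope + shape
    assert model.aic_ == pytest.approx(-2 * model.loglik_ + 2 * k, abs=1e-10)
    assert model.bic_ == pytest.approx(
        -2 * model.loglik_ + k * np.log(y.size), abs=1e-10
    )


def test_rank_deficient_design_rejected():
    X, y = simulate_regression_data((1.3, 1.4), 2.0, 0.5, 100, seed=1)
    X_dup = np.column_stack([X, X[:, 0]])
    with pytest.raises(ValueError, match="rank"):
        NBUWQuantileRegressor().fit(X_dup, y)


def test_sklearn_compatibility():
    from sklearn.base import clone
    from sklearn.model_selection import cross_val_score

    X, y = simulate_regression_data((1.3, 1.4), 2.0, 0.5, 300, seed=2)
    model = NBUWQuantileRegressor(q=0.5)
    assert clone(model).get_params()["q"] == 0.5
    scores = cross_val_score(model, X, y, cv=3)
    assert np.all(np.isfinite(scores))


def test_summary_frame_shape():
    X, y = simulate_regression_data((1.3, 1.4), 2.0, 0.5, 300, seed=2)
    frame = NBUWQuantileRegressor().fit(X, y).summary_frame()
    assert list(frame.columns) == ["estimate", "std_error", "z", "p_value"]
    assert len(frame) == 3
    assert ((frame["p_value"] >= 0) & (frame["p_value"] <= 1)).all()


@pytest.mark.parametrize("q", [0.1, 0.5, 0.9])
def test_sampling_from_fitted_model(q):
    X, y = simulate_regression_data((0.7, 0.4), 3.0, q, 5000, seed=17)
    model = NBUWQuantileRegressor(q=q).fit(X, y)
    draws = model.sample(X, random_state=1)
    assert np.all((draws > 0) & (draws < 1))
    assert np.mean(draws < model.predict(X)) == pytest.approx(q, abs=0.03)


R_ORACLE = textwrap.dedent(
    """
    args <- commandArgs(trailingOnly=TRUE)
    d <- read.csv(args[1])
    q <- as.numeric(args[2])
    nll <- function(p) {
      beta <- exp(p[1]); delta <- p[2:3]
      eta <- delta[1] + delta[2]*d$x1
      mu <- 1/(1+exp(-eta))
      a <- -(1/mu - 1)^(-beta) * log(q)
      t <- (1-d$y)/d$y
      -sum(log(a) + log(beta) + (beta-1)*log(t) - 2*log(d$y) - a*t^beta)
    }
    r <- optim(c(0,0,0), nll, method="BFGS",
               control=list(maxit=1000, reltol=1e-14))
    cat(sprintf("%.10f", c(exp(r$par[1]), r$par[2], r$par[3], -r$value)),
        sep="\\n")
    """
)


def test_regression_mle_matches_r_optim(tmp_path):
    """Independent cross-language oracle: R's optim on the same likelihood
    written from scratch must find the same optimum."""
    X, y = simulate_regression_data((1.3, 1.4), 2.0, 0.5, 300, seed=42)
    csv = tmp_path / "reg.csv"
    np.savetxt(csv, np.column_stack([y, X]), delimiter=",",
               header="y,x1", comments="")
    script = tmp_path / "fit.R"
    script.write_text(R_ORACLE)
    try:
        out = subprocess.run(
            ["Rscript", str(script), str(csv), "0.5"],
            capture_output=True, text=True, timeout=120, check=True,
        )
    except (FileNotFoundError, subprocess.CalledProcessError) as exc:
        pytest.skip(f"Rscript unavailable: {exc}")
    beta_r, d0_r, d1_r, ll_r = map(float, out.stdout.split())
    model = NBUWQuantileRegressor(q=0.5).fit(X, y)
    assert model.shape_ == pytest.approx(beta_r, abs=1e-4)
    assert model.intercept_ == pytest.approx(d0_r, abs=1e-4)
    assert model.coef_[0] == pytest.approx(d1_r, abs=1e-4)
    assert model.loglik_ == pytest.approx(ll_r, abs=1e-6)
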