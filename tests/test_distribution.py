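"""Core distribution functions: closed forms, identities, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from nbuw.distribution import (
    NBUWParams,
    classical_hazard,
    nbuw_cdf,
    nbuw_logpdf,
    nbuw_pdf,
    nbuw_ppf,
    nbuw_rvs,
    reversed_hazard,
)


class _NumericOracle(stats.rv_continuous):
    """scipy generic machinery driven by the CDF alone.

    Everything else (ppf, pdf, moments) is derived numerically by scipy,
    independently of this package's closed forms.
    """

    def _cdf(self, x, alpha, beta):
        return np.exp(-alpha * ((1.0 - x) / x) ** beta)

    def _argcheck(self, alpha, beta):
        return (alpha > 0) & (beta > 0)


_oracle = _NumericOracle(a=1e-12, b=1.0, name="nbuw_oracle")


def test_cdf_closed_form_points():
    # (1-x)/x = 1 at x=1/2, so F = exp(-alpha) regardless of beta
    assert nbuw_cdf(0.5, 0.5, 0.75) == pytest.approx(np.exp(-0.5), abs=1e-12)
    assert nbuw_cdf(1.0, 2.0, 3.0) == 1.0
    # median of the alpha=beta=1 case is 1/(1+log 2)
    assert nbuw_cdf(0.5906, 1.0, 1.0) == pytest.approx(0.5, abs=1e-3)


def test_pdf_closed_form_point():
    # all power terms collapse at x=1/2 except x**-2 = 4
    assert nbuw_pdf(0.5, 1.0, 1.0) == pytest.approx(4 * np.exp(-1), rel=1e-12)


def test_quantile_closed_form():
    assert nbuw_ppf(0.5, 1.0, 1.0) == pytest.approx(1 / (1 + np.log(2)),
                                                    rel=1e-12)
    # q = exp(-alpha) maps to the midpoint for any shape
    for beta in (0.5, 1.0, 3.7):
        assert nbuw_ppf(np.exp(-1.3), 1.3, beta) == pytest.approx(0.5,
                                                                  abs=1e-12)


def test_quantile_cdf_roundtrip(params):
    alpha, beta = params
    x = np.array([0.1, 0.35, 0.5, 0.75, 0.9])
    c = np.asarray(nbuw_cdf(x, alpha, beta))
    interior = (c > 1e-300) & (c < 1.0)  # cdf underflows in the deep tail
    assert nbuw_ppf(c[interior], alpha, beta) == pytest.approx(
        x[interior], abs=1e-10
    )
    q = np.array([0.01, 0.25, 0.5, 0.75, 0.99])
    assert nbuw_cdf(nbuw_ppf(q, alpha, beta), alpha, beta) == pytest.approx(
        q, abs=1e-10
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    alpha=st.floats(0.05, 20.0),
    beta=st.floats(0.05, 20.0),
    q=st.floats(0.001, 0.999),
)
def test_quantile_inverts_cdf_property(alpha, beta, q):
    x = nbuw_ppf(q, alpha, beta)
    assert 0.0 < x < 1.0
    # tolerance limited by float conditioning when x sits next to 1
    assert nbuw_cdf(x, alpha, beta) == pytest.approx(q, abs=2e-6)


def test_pdf_normalizes(params):
    alpha, beta = params
    total, _ = integrate.quad(
        lambda x: nbuw_pdf(x, alpha, beta), 0, 1, limit=200
    )
    assert total == pytest.approx(1.0, abs=1e-8)


def test_pdf_is_cdf_derivative():
    h = 1e-6
    for x, alpha, beta in [(0.3, 2.0, 1.75), (0.6, 0.5, 0.75)]:
        numeric = (nbuw_cdf(x + h, alpha, beta) - nbuw_cdf(x - h, alpha, beta)) / (2 * h)
        assert nbuw_pdf(x, alpha, beta) == pytest.approx(numeric, rel=1e-6)


def test_ppf_matches_numeric_oracle():
    """Closed-form quantiles agree with scipy's generic CDF inversion."""
    for q in (0.1, 0.5, 0.9):
        assert nbuw_ppf(q, 1.5, 1.25) == pytest.approx(
            _oracle.ppf(q, 1.5, 1.25), abs=1e-8
        )


def test_moments_match_numeric_oracle():
    mean_oracle = _oracle.moment(1, 1.5, 1.25)
    x = nbuw_rvs(1.5, 1.25, 200_000, random_state=0)
    assert x.mean() == pytest.approx(mean_oracle, abs=0.003)


def test_reversed_hazard_identity():
    # the exponential factor cancels in f/F, pointwise to machine precision
    for x in (0.2, 0.4, 0.8):
        assert reversed_hazard(x, 1.75, 1.5) == pytest.approx(
            nbuw_pdf(x, 1.75, 1.5) / nbuw_cdf(x, 1.75, 1.5), rel=1e-12
        )
    assert reversed_hazard(0.5, 1.0, 1.0) == pytest.approx(4.0, rel=1e-12)


def test_reversed_vs_classical_hazard_differ():
    """The printed rate formula is f/F, not the classical f/(1-F)."""
    classical = classical_hazard(0.5, 1.0, 1.0)
    assert classical == pytest.approx(
        4 * np.exp(-1) / (1 - np.exp(-1)), rel=1e-10
    )
    assert reversed_hazard(0.5, 1.0, 1.0) != pytest.approx(classical, rel=0.1)


def test_rvs_deterministic_and_distributed():
    a = nbuw_rvs(0.5, 0.75, 1000, random_state=7)
    b = nbuw_rvs(0.5, 0.75, 1000, random_state=7)
    np.testing.assert_array_equal(a, b)
    big = nbuw_rvs(0.5, 0.75, 100_000, random_state=1)
    stat = stats.kstest(big, lambda t: nbuw_cdf(t, 0.5, 0.75)).statistic
    assert stat < 1.63 / np.sqrt(big.size)  # 1% KS critical value


def test_rvs_median_matches_quantile():
    x = nbuw_rvs(1.0, 1.0, 100_000, random_state=3)
    assert np.median(x) == pytest.approx(0.5906, abs=0.005)


def test_variance_decreases_in_beta():
    # with alpha=1 the distribution concentrates at 1/2 as beta grows
    variances = []
    for beta in (0.5, 1.0, 2.0, 4.0, 8.0):
        x = nbuw_rvs(1.0, beta, 50_000, random_state=11)
        variances.append(x.var())
    assert all(v1 > v2 for v1, v2 in zip(variances, variances[1:]))


def test_domain_validation():
    with pytest.raises(ValueError):
        nbuw_cdf(0.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        nbuw_cdf(1.2, 1.0, 1.0)
    with pytest.raises(ValueError):
        nbuw_ppf(1.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        nbuw_pdf(0.5, -1.0, 1.0)
    with pytest.raises(ValueError):
        NBUWParams(alpha=0.0, beta=1.0)


def test_logpdf_boundary_sentinels():
    assert nbuw_logpdf(1.0, 1.0, 0.5) == np.inf
    assert nbuw_logpdf(1.0, 1.0, 2.0) == -np.inf
    assert nbuw_logpdf(1.0, 1.3, 1.0) == pytest.approx(np.log(1.3))


def test_logpdf_consistency():
    x = np.linspace(0.05, 0.95, 7)
    assert np.exp(nbuw_logpdf(x, 0.75, 0.5)) == pytest.approx(
        nbuw_pdf(x, 0.75, 0.5), rel=1e-12
    )
    assert nbuw_logpdf(0.5, 1.0, 1.0) == pytest.approx(np.log(4) - 1,
                                                       rel=1e-12)
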