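"""Moments, moment generating function and entropies of the NBUW law.

Adaptive quadrature is the authoritative route everywhere.  Raw moments and
the MGF integrate through the quantile substitution ``E[g(X)] = int_0^1
g(Q(u)) du``, which removes the boundary singularities of the density.
Entropies integrate ``f(x)**theta`` directly on (0, 1).

The distribution's density also admits a formal double series in beta
densities, with coefficients

    Delta_ij = (-1)**(i+j) / j! * C(beta-1, i) * alpha**j,

giving raw moments ``alpha*beta * sum_ij Delta_ij * B(i+m-beta*j-beta,
beta*j+1)``.  The first beta-function argument is negative for many (i, j),
where B is undefined, so the series cannot be summed literally for general
parameters.  It is provided as a *diagnostic* representation only: terms
with non-positive first argument are excluded, the truncation bound and the
achieved tail increment are reported, and a ConvergenceError is raised when
the guarded sum is untrustworthy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from .distribution import _validate_params, nbuw_logpdf, nbuw_ppf

__all__ = [
    "ConvergenceError",
    "DivergenceError",
    "SeriesResult",
    "raw_moment",
    "mean_variance",
    "mgf",
    "renyi_entropy",
    "q_entropy",
    "shannon_entropy",
]


class ConvergenceError(RuntimeError):
    """Raised when the diagnostic series fails its truncation tolerance."""


class DivergenceError(RuntimeError):
    """Raised when an entropy integral is non-integrable."""


@dataclass(frozen=True)
class SeriesResult:
    """Value of a guarded series with its truncation diagnostics."""

    value: float
    max_index: int
    tail_increment: float
    n_terms: int


def _quad_expectation(g, alpha, beta, **kwargs):
    """int_0^1 g(Q(u)) du by adaptive quadrature (smooth integrand)."""
    val, _ = integrate.quad(
        lambda u: g(nbuw_ppf(u, alpha, beta)), 0.0, 1.0, limit=200, **kwargs
    )
    return val


def raw_moment(m, alpha, beta, method="quadrature", max_index=50, tol=1e-10):
    """m-th raw moment E[X**m].

    ``method="quadrature"`` (authoritative) integrates x**m against the
    density through the quantile substitution.  ``method="series"``
    evaluates the guarded beta-function double series and returns a
    :class:`SeriesResult`.
    """
    _validate_params(alpha, beta)
    m = int(m)
    if m < 0:
        raise ValueError("moment order must be a non-negative integer")
    if method == "quadrature":
        if m == 0:
            return _quad_expectation(lambda x: np.ones_like(x), alpha, beta)
        return _quad_expectation(lambda x: x**m, alpha, beta)
    if method == "series":
        return _series_moment(m, alpha, beta, max_index=max_index, tol=tol)
    raise ValueError(f"unknown method {method!r}")


def _series_moment(m, alpha, beta, max_index=50, tol=1e-10):
    log_alpha = np.log(alpha)
    prefactor = alpha * beta
    total = 0.0
    n_terms = 0
    tail = 0.0
    for i in range(max_index + 1):
        comb = special.binom(beta - 1.0, i)
        if comb == 0.0:
            continue
        for j in range(max_index + 1):
            a = i + m - beta * j - beta
            if a <= 0:
                continue
            log_mag = (
                j * log_alpha
                - special.gammaln(j + 1)
                + np.log(abs(comb))
                + special.betaln(a, beta * j + 1.0)
            )
            sign = (1.0 if (i + j) % 2 == 0 else -1.0) * np.sign(comb)
            term = prefactor * sign * np.exp(log_mag)
            if not np.isfinite(term):
                raise ConvergenceError(
                    f"non-finite series term at (i={i}, j={j})"
                )
            total += term
            n_terms += 1
            if i == max_index or j == max_index:
                tail = max(tail, abs(term))
    if n_terms == 0:
        raise ConvergenceError(
            "no admissible series terms (all beta arguments non-positive)"
        )
    if tail > tol:
        raise ConvergenceError(
            f"tail increment {tail:.3e} exceeds tolerance {tol:.1e} "
            f"at truncation bound {max_index}"
        )
    return SeriesResult(total, max_index, tail, n_terms)


def mean_variance(alpha, beta):
    """(mean, variance) from the first two quadrature moments."""
    m1 = raw_moment(1, alpha, beta)
    m2 = raw_moment(2, alpha, beta)
    return m1, m2 - m1 * m1


def mgf(eta, alpha, beta):
    """Moment generating function E[exp(eta*X)]; finite for all eta."""
    _validate_params(alpha, beta)
    eta = float(eta)
    return _quad_expectation(lambda x: np.exp(eta * x), alpha, beta)


def _density_power_integral(theta, alpha, beta):
    """int_0^1 f(x)**theta dx with boundary-divergence detection.

    Near x=1 the density behaves like ((1-x)/x)**(beta-1); the integral of
    its theta power converges iff theta*(beta-1) > -1.
    """
    if theta * (beta - 1.0) <= -1.0:
        raise DivergenceError(
            f"integral of f**theta diverges at x=1 for theta={theta}, "
            f"beta={beta} (theta*(beta-1) <= -1)"
        )

    def integrand(x):
        with np.errstate(over="ignore"):
            return np.exp(theta * nbuw_logpdf(x, alpha, beta))

    val, _ = integrate.quad(
        integrand, 0.0, 1.0, limit=400, points=[1e-6, 0.5, 1.0 - 1e-6]
    )
    return val


def renyi_entropy(theta, alpha, beta, method="quadrature", max_index=50, tol=1e-10):
    """Renyi entropy (1/(1-theta)) * log int f**theta, theta > 0, != 1.

    The series route uses starred coefficients ``Delta*_ij =
    (-1)**(i+j)/j! * C(beta*theta-theta, i) * (alpha*theta)**j *
    (alpha*beta)**theta`` and beta arguments ``(i - beta*j - beta*theta -
    theta + 1, beta*j + 1)`` (the +1 required by the x**(a-1) convention),
    guarded like the moment series.  Diagnostic only.
    """
    _validate_params(alpha, beta)
    theta = float(theta)
    if theta <= 0 or theta == 1.0:
        raise ValueError("Renyi order must be positive and != 1")
    if method == "quadrature":
        integral = _density_power_integral(theta, alpha, beta)
        return np.log(integral) / (1.0 - theta)
    if method == "series":
        sr = _renyi_series(theta, alpha, beta, max_index=max_index, tol=tol)
        return np.log(sr.value) / (1.0 - theta)
    raise ValueError(f"unknown method {method!r}")


def _renyi_series(theta, alpha, beta, max_index=50, tol=1e-10):
    log_at = np.log(alpha * theta)
    prefactor = (alpha * beta) ** theta
    total = 0.0
    n_terms = 0
    tail = 0.0
    for i in range(max_index + 1):
        comb = special.binom(beta * theta - theta, i)
        if comb == 0.0:
            continue
        for j in range(max_index + 1):
            a = i - beta * j - beta * theta - theta + 1.0
            if a <= 0:
                continue
            log_mag = (
                j * log_at
                - special.gammaln(j + 1)
                + np.log(abs(comb))
                + special.betaln(a, beta * j + 1.0)
            )
            sign = (1.0 if (i + j) % 2 == 0 else -1.0) * np.sign(comb)
            term = prefactor * sign * np.exp(log_mag)
            if not np.isfinite(term):
                raise ConvergenceError(
                    f"non-finite series term at (i={i}, j={j})"
                )
            total += term
            n_terms += 1
            if i == max_index or j == max_index:
                tail = max(tail, abs(term))
    if n_terms == 0:
        raise ConvergenceError(
            "no admissible series terms (all beta arguments non-positive)"
        )
    if tail > tol:
        raise ConvergenceError(
            f"tail increment {tail:.3e} exceeds tolerance {tol:.1e}"
        )
    return SeriesResult(total, max_index, tail, n_terms)


def q_entropy(q_order, alpha, beta):
    """Tsallis-type q-entropy (1/(1-q)) * log(1 - int f**q).

    Raises a domain error (with the computed integral reported) whenever
    ``int f**q >= 1``, where the logarithm is undefined.
    """
    _validate_params(alpha, beta)
    q_order = float(q_order)
    if q_order <= 0 or q_order == 1.0:
        raise ValueError("q-entropy order must be positive and != 1")
    integral = _density_power_integral(q_order, alpha, beta)
    if integral >= 1.0:
        raise ValueError(
            f"q-entropy undefined: int f**q = {integral:.6f} >= 1"
        )
    return np.log1p(-integral) / (1.0 - q_order)


def shannon_entropy(alpha, beta):
    """Differential entropy -E[log f(X)], the theta -> 1 Renyi limit."""
    _validate_params(alpha, beta)
    return -_quad_expectation(
        lambda x: nbuw_logpdf(x, alpha, beta), alpha, beta
    )
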