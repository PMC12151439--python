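"""The bounded unit Weibull distribution on (0, 1].

A Weibull random variable ``Y`` on (0, inf) mapped through ``X = 1/(1+Y)``
yields a two-parameter distribution for proportions with closed-form CDF,
quantile function and density::

    F(x; a, b) = exp(-a * ((1-x)/x)**b),        0 < x <= 1,  a, b > 0
    f(x; a, b) = a*b * ((1-x)/x)**(b-1) * x**(-2) * F(x; a, b)

``a`` (``alpha``) acts as a scale-like parameter, ``b`` (``beta``) as the
shape.  The density can be bathtub-shaped, right-skewed or unimodal; for
``alpha = 1`` mass concentrates at ``x = 1/2`` as ``beta`` grows.

All functions are vectorized over ``x`` and validate the support strictly:
0 is outside the support, 1 is in the support of the CDF but is a boundary
point of the density (infinite for ``beta < 1``, zero for ``beta > 1``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NBUWParams",
    "nbuw_cdf",
    "nbuw_pdf",
    "nbuw_logpdf",
    "nbuw_ppf",
    "nbuw_sf",
    "reversed_hazard",
    "classical_hazard",
    "nbuw_rvs",
]

#: observations exactly equal to 1 are clamped to 1 - BOUNDARY_EPS by
#: likelihood code (real proportion data may contain exact ones).
BOUNDARY_EPS = 1e-10


def _validate_params(alpha, beta) -> None:
    # alpha may be a vector (the quantile-parameterized form maps a vector
    # of conditional quantiles to per-observation scales); beta is scalar
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not (np.all(np.isfinite(alpha)) and np.all(alpha > 0)):
        raise ValueError("alpha must be positive and finite")
    if not (np.all(np.isfinite(beta)) and np.all(beta > 0)):
        raise ValueError("beta must be positive and finite")


@dataclass(frozen=True)
class NBUWParams:
    """Validated (alpha, beta) parameter pair, both strictly positive."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        _validate_params(self.alpha, self.beta)

    def as_tuple(self) -> tuple[float, float]:
        return (float(self.alpha), float(self.beta))


def _check_support(x: np.ndarray, allow_one: bool) -> None:
    hi_bad = (x > 1) if allow_one else (x >= 1)
    if np.any((x <= 0) | hi_bad | ~np.isfinite(x)):
        interval = "(0, 1]" if allow_one else "(0, 1)"
        raise ValueError(f"observations must lie in {interval}")


def _log_odds(x: np.ndarray) -> np.ndarray:
    """log((1-x)/x); -inf at x=1."""
    with np.errstate(divide="ignore"):
        return np.log1p(-x) - np.log(x)


def nbuw_cdf(x, alpha, beta):
    """Distribution function ``exp(-alpha*((1-x)/x)**beta)`` on (0, 1]."""
    _validate_params(alpha, beta)
    x = np.asarray(x, dtype=float)
    _check_support(x, allow_one=True)
    logt = _log_odds(x)
    with np.errstate(over="ignore"):
        z = alpha * np.exp(beta * logt)
    return np.exp(-z)[()]


def nbuw_sf(x, alpha, beta):
    """Survival function 1 - F(x), computed as -expm1 for accuracy."""
    _validate_params(alpha, beta)
    x = np.asarray(x, dtype=float)
    _check_support(x, allow_one=True)
    logt = _log_odds(x)
    with np.errstate(over="ignore"):
        z = alpha * np.exp(beta * logt)
    return -np.expm1(-z)[()]


def nbuw_logpdf(x, alpha, beta):
    """Log-density, stable in log space for large ``beta``.

    At the boundary x=1 the density diverges for ``beta < 1`` (+inf is
    returned), vanishes for ``beta > 1`` (-inf), and equals ``alpha`` for
    ``beta == 1``.
    """
    _validate_params(alpha, beta)
    x = np.asarray(x, dtype=float)
    _check_support(x, allow_one=True)
    logt = _log_odds(x)
    with np.errstate(over="ignore", invalid="ignore"):
        out = (
            np.log(alpha)
            + np.log(beta)
            + (beta - 1.0) * logt
            - 2.0 * np.log(x)
            - alpha * np.exp(beta * logt)
        )
    at_one = x == 1.0
    if np.any(at_one):
        if beta < 1:
            boundary = np.inf
        elif beta > 1:
            boundary = -np.inf
        else:
            boundary = np.log(alpha)
        out = np.where(at_one, boundary, out)
    return out[()]


def nbuw_pdf(x, alpha, beta):
    """Density ``alpha*beta*((1-x)/x)**(beta-1) * x**-2 * F(x)``."""
    with np.errstate(over="ignore"):
        return np.exp(nbuw_logpdf(x, alpha, beta))


def nbuw_ppf(q, alpha, beta):
    """Quantile function ``[1 + (-log(q)/alpha)**(1/beta)]**-1`` on (0, 1)."""
    _validate_params(alpha, beta)
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1) | ~np.isfinite(q)):
        raise ValueError("quantile levels must lie strictly in (0, 1)")
    # (-log q / alpha)**(1/beta) in log space to dodge overflow for small q
    log_ratio = (np.log(-np.log(q)) - np.log(alpha)) / beta
    with np.errstate(over="ignore"):
        r = np.exp(log_ratio)
    return (1.0 / (1.0 + r))[()]


def reversed_hazard(x, alpha, beta):
    """The rate ``f(x)/F(x) = alpha*beta*((1-x)/x)**(beta-1)*x**-2``.

    This is the formula the source model presents as its "hazard rate
    function"; algebraically it is the *reversed* hazard f/F (the
    exponential factor cancels), not the classical hazard f/(1-F).  Both
    are exposed; see :func:`classical_hazard`.
    """
    _validate_params(alpha, beta)
    x = np.asarray(x, dtype=float)
    _check_support(x, allow_one=False)
    logt = _log_odds(x)
    with np.errstate(over="ignore"):
        return (alpha * beta * np.exp((beta - 1.0) * logt) / np.square(x))[()]


#: the formula presented as the model's HRF; see reversed_hazard docstring.
hazard_rate = reversed_hazard


def classical_hazard(x, alpha, beta):
    """Classical hazard rate f(x)/(1-F(x))."""
    return nbuw_pdf(x, alpha, beta) / nbuw_sf(x, alpha, beta)


def nbuw_rvs(alpha, beta, size=1, random_state=None):
    """Inverse-transform sampling via the closed-form quantile function.

    ``random_state`` accepts anything ``numpy.random.default_rng`` does
    (int seed, Generator, SeedSequence, None).
    """
    _validate_params(alpha, beta)
    rng = np.random.default_rng(random_state)
    u = rng.random(size)
    # guard the measure-zero event u == 0 (log(-log u) undefined)
    u = np.clip(u, 1e-300, None)
    return nbuw_ppf(u, alpha, beta)
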