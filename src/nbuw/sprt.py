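"""Wald sequential probability ratio test for the NBUW shape parameter.

Tests H0: beta = beta0 against H1: beta = beta1 (beta1 > beta0) with the
scale alpha known.  Each observation contributes the log-likelihood-ratio
increment

    xi = log(b1/b0) + (b1-b0)*log((1-x)/x) - a*((1-x)/x)**b1
         + a*((1-x)/x)**b0,

sampling stops the first time the cumulative sum leaves (log B, log A)
with A = (1-psi)/delta, B = psi/(1-delta), where delta and psi are the
nominal type-I and type-II error probabilities.  Overshoot is not
corrected (the plain Wald approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .distribution import _validate_params, nbuw_ppf, nbuw_rvs

__all__ = [
    "SPRTConfig",
    "SPRTResult",
    "increment",
    "boundaries",
    "run",
    "expected_increment",
    "oc_function",
    "asn",
    "simulate_runs",
]


@dataclass(frozen=True)
class SPRTConfig:
    """Hypotheses and error rates for the sequential test.

    alpha is the known scale; beta0 < beta1 are the hypothesized shapes;
    delta and psi are the nominal type-I and type-II error probabilities.
    """

    alpha: float
    beta0: float
    beta1: float
    delta: float = 0.05
    psi: float = 0.05

    def __post_init__(self) -> None:
        _validate_params(self.alpha, self.beta0)
        _validate_params(self.alpha, self.beta1)
        if not self.beta1 > self.beta0:
            raise ValueError("require beta1 > beta0")
        for name in ("delta", "psi"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class SPRTResult:
    n_used: int
    log_lambda: float
    decision: str  # "accept_H0" | "reject_H0" | "continue"


def increment(x, config: SPRTConfig):
    """Per-observation log-likelihood-ratio increment xi (vectorized)."""
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("SPRT observations must lie strictly in (0, 1)")
    logt = np.log1p(-x) - np.log(x)
    a, b0, b1 = config.alpha, config.beta0, config.beta1
    return (
        np.log(b1 / b0)
        + (b1 - b0) * logt
        - a * np.exp(b1 * logt)
        + a * np.exp(b0 * logt)
    )[()]


def boundaries(config: SPRTConfig) -> tuple[float, float]:
    """(log A, log B) with A=(1-psi)/delta, B=psi/(1-delta)."""
    log_a = np.log((1.0 - config.psi) / config.delta)
    log_b = np.log(config.psi / (1.0 - config.delta))
    return log_a, log_b


def run(data_stream, config: SPRTConfig) -> SPRTResult:
    """Consume observations until a Wald boundary is hit.

    Returns decision "continue" with the accumulated statistic if the
    stream is exhausted strictly inside (log B, log A).
    """
    log_a, log_b = boundaries(config)
    total = 0.0
    n = 0
    for x in data_stream:
        total += float(increment(x, config))
        n += 1
        if total >= log_a:
            return SPRTResult(n, total, "reject_H0")
        if total <= log_b:
            return SPRTResult(n, total, "accept_H0")
    return SPRTResult(n, total, "continue")


def expected_increment(beta_true, config: SPRTConfig, method="quadrature",
                       n_draws=200_000, seed=0):
    """E_beta[xi] under NBUW(alpha, beta_true).

    Quadrature integrates xi(Q(u)) du (smooth substitution).  The
    Monte-Carlo fallback returns (estimate, standard_error).
    """
    _validate_params(config.alpha, beta_true)
    if method == "quadrature":
        val, _ = integrate.quad(
            lambda u: increment(
                nbuw_ppf(u, config.alpha, beta_true), config
            ),
            0.0,
            1.0,
            limit=200,
        )
        return val
    if method == "monte_carlo":
        x = nbuw_rvs(config.alpha, beta_true, size=n_draws, random_state=seed)
        xi = increment(x, config)
        return xi.mean(), xi.std(ddof=1) / np.sqrt(n_draws)
    raise ValueError(f"unknown method {method!r}")


def simulate_runs(config: SPRTConfig, beta_true, n_runs, seed=0,
                  max_n=100_000, chunk=128):
    """Vectorized Monte-Carlo of the sequential test.

    Returns (decisions, n_used, final_llr): decisions is an int8 array
    with 1 for reject_H0, 0 for accept_H0, -1 for truncated at max_n;
    final_llr is the cumulative log likelihood ratio at stopping
    (including the boundary overshoot).
    """
    rng = np.random.default_rng(seed)
    log_a, log_b = boundaries(config)
    state = np.zeros(n_runs)
    n_used = np.zeros(n_runs, dtype=np.int64)
    decisions = np.full(n_runs, -1, dtype=np.int8)
    final_llr = np.zeros(n_runs)
    active = np.arange(n_runs)
    consumed = 0
    while active.size and consumed < max_n:
        x = nbuw_rvs(
            config.alpha, beta_true, size=(active.size, chunk),
            random_state=rng,
        )
        cum = state[active, None] + np.cumsum(increment(x, config), axis=1)
        hit_hi = cum >= log_a
        hit_lo = cum <= log_b
        hit = hit_hi | hit_lo
        any_hit = hit.any(axis=1)
        first = np.argmax(hit, axis=1)
        done = active[any_hit]
        fdone = first[any_hit]
        n_used[done] += fdone + 1
        decisions[done] = np.where(
            hit_hi[any_hit, fdone], np.int8(1), np.int8(0)
        )
        final_llr[done] = cum[any_hit, fdone]
        still = active[~any_hit]
        state[still] = cum[~any_hit, -1]
        final_llr[still] = cum[~any_hit, -1]
        n_used[still] += chunk
        active = still
        consumed += chunk
    return decisions, n_used, final_llr


def oc_function(beta_true, config: SPRTConfig, method="nominal",
                n_runs=5000, seed=0, max_n=100_000):
    """Operating characteristic L(beta) = P(accept H0 | beta).

    The nominal (Wald) values are defined only at the hypothesized points:
    L(beta0) = 1 - delta and L(beta1) = psi.  Any other beta requires the
    Monte-Carlo method.
    """
    if method == "nominal":
        if np.isclose(beta_true, config.beta0):
            return 1.0 - config.delta
        if np.isclose(beta_true, config.beta1):
            return config.psi
        raise ValueError(
            "nominal OC values exist only at beta0/beta1; "
            "use method='monte_carlo' for other parameter values"
        )
    if method == "monte_carlo":
        decisions, _, _ = simulate_runs(
            config, beta_true, n_runs, seed=seed, max_n=max_n
        )
        finished = decisions >= 0
        return float(np.mean(decisions[finished] == 0))
    raise ValueError(f"unknown method {method!r}")


def asn(hypothesis, config: SPRTConfig, form="printed"):
    """Average sample number E(N) under "H0" or "H1".

    Wald's identity gives E(N) = [L*logB + (1-L)*logA] / E(xi).  Under H0
    (L = 1-delta) the numerator is delta*logA + (1-delta)*logB.  Under H1
    the standard form uses L = psi (numerator psi*logB + (1-psi)*logA);
    the source model prints delta*logB + (1-psi)*logA instead, mixing the
    two error rates.  ``form="printed"`` follows the printed formula,
    ``form="standard"`` the Wald one; they coincide under H0 and whenever
    delta == psi.

    Note: the numerator uses the no-overshoot approximation of E(S_N).
    When per-observation increments are large relative to the boundaries
    (well-separated hypotheses), overshoot inflates the true |E(S_N)| and
    the nominal ASN can substantially underestimate the Monte-Carlo mean
    stopping time; Wald's identity E(S_N) = E(N) * E(xi) itself remains
    exact (see simulate_runs, which returns the stopped statistic).
    """
    log_a, log_b = boundaries(config)
    d, p = config.delta, config.psi
    if hypothesis == "H0":
        numerator = d * log_a + (1.0 - d) * log_b
        denom = expected_increment(config.beta0, config)
    elif hypothesis == "H1":
        if form == "printed":
            numerator = d * log_b + (1.0 - p) * log_a
        elif form == "standard":
            numerator = p * log_b + (1.0 - p) * log_a
        else:
            raise ValueError(f"unknown form {form!r}")
        denom = expected_increment(config.beta1, config)
    else:
        raise ValueError("hypothesis must be 'H0' or 'H1'")
    if abs(denom) < 1e-12:
        raise ZeroDivisionError(
            "expected increment is numerically zero; ASN undefined"
        )
    return numerator / denom
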