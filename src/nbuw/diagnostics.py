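"""Residuals and goodness-of-fit for fitted NBUW models.

Quantile residuals are Phi^-1(G(y_i)) with G the fitted CDF; for a
continuous response no randomization is involved, so they are
deterministic PIT transforms and standard normal under a correct model.
Cox-Snell residuals -log(1 - G(y_i)) are unit exponential under a correct
model.  Both are monotone transforms of the same PIT values, so
``cox_snell = -log(1 - Phi(quantile_residual))`` holds identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .distribution import nbuw_cdf
from .mle import NBUWMLE, prepare_unit_data

_PIT_CLIP = 1e-12


@dataclass(frozen=True)
class ResidualSet:
    quantile_residuals: np.ndarray
    cox_snell: np.ndarray
    ks_statistic: float
    ks_pvalue: float


def _clip_pit(g):
    g = np.asarray(g, dtype=float)
    out_of_range = (g <= 0.0) | (g >= 1.0)
    if np.any(out_of_range):
        warnings.warn(
            f"{int(out_of_range.sum())} PIT value(s) at 0 or 1 clamped to "
            f"[{_PIT_CLIP:g}, 1-{_PIT_CLIP:g}]",
            stacklevel=3,
        )
    return np.clip(g, _PIT_CLIP, 1.0 - _PIT_CLIP)


def quantile_residuals_from_pit(g):
    """Phi^-1 of PIT values, clamped away from {0, 1}."""
    return stats.norm.ppf(_clip_pit(g))


def cox_snell_from_pit(g):
    """-log(1 - G) of PIT values, clamped away from {0, 1}."""
    return -np.log1p(-_clip_pit(g))


def model_pit(model, X=None, y=None):
    """PIT values G(y_i) from a fitted model.

    ``model`` is either a fitted NBUWQuantileRegressor (pass X and y) or
    a fitted NBUWMLE (pass the sample as y, X ignored).
    """
    if hasattr(model, "predict_cdf"):
        if X is None or y is None:
            raise ValueError("regression models require both X and y")
        return np.asarray(model.predict_cdf(X, y))
    if isinstance(model, NBUWMLE) or hasattr(model, "alpha_"):
        data = y if y is not None else X
        data, _ = prepare_unit_data(np.asarray(data, dtype=float).ravel())
        return np.asarray(nbuw_cdf(data, model.alpha_, model.beta_))
    raise TypeError(f"unsupported model type {type(model).__name__}")


def residual_analysis(model, X=None, y=None) -> ResidualSet:
    """Quantile and Cox-Snell residuals plus a normal KS check."""
    g = model_pit(model, X, y)
    r = quantile_residuals_from_pit(g)
    e = cox_snell_from_pit(g)
    stat, p = ks_gof(r, reference="std_normal")
    return ResidualSet(r, e, stat, p)


def ks_gof(sample, reference="std_normal", cdf=None, args=()):
    """One-sample Kolmogorov-Smirnov test.

    ``reference`` is one of "std_normal", "unit_exponential" or
    "fitted_nbuw_cdf" (the latter requires ``args=(alpha, beta)``), or
    pass an arbitrary callable CDF via ``cdf``.  Returns (statistic,
    asymptotic p-value).  Note: the p-value does not account for
    estimated parameters (the naive one-sample test).
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size < 5:
        raise ValueError("need at least 5 observations for the KS test")
    if np.unique(sample).size < sample.size:
        warnings.warn("ties present in nominally continuous data",
                      stacklevel=2)
    if cdf is None:
        if reference == "std_normal":
            cdf = stats.norm.cdf
        elif reference == "unit_exponential":
            cdf = stats.expon.cdf
        elif reference == "fitted_nbuw_cdf":
            alpha, beta = args
            args = ()
            cdf = lambda x: nbuw_cdf(x, alpha, beta)  # noqa: E731
        else:
            raise ValueError(f"unknown reference {reference!r}")
    res = stats.kstest(sample, cdf, args=args)
    return float(res.statistic), float(res.pvalue)


def information_criteria(loglik, n_params, n_obs):
    """(AIC, BIC) = (-2l + 2k, -2l + k log n)."""
    if n_params < 1 or n_obs < n_params:
        raise ValueError("require 1 <= n_params <= n_obs")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * np.log(n_obs)
    return aic, bic


def half_normal_plot(quantile_residuals, n_sim=100, seed=None, ax=None):
    """Half-normal plot of |quantile residuals| with a simulated envelope.

    Orders |r| against half-normal plotting positions and overlays
    pointwise min/max envelope bands from ``n_sim`` standard-normal
    simulations.  Returns the matplotlib axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    r = np.sort(np.abs(np.asarray(quantile_residuals, dtype=float)))
    n = r.size
    positions = stats.halfnorm.ppf((np.arange(1, n + 1) - 0.5) / n)
    rng = np.random.default_rng(seed)
    sims = np.sort(np.abs(rng.standard_normal((n_sim, n))), axis=1)
    lo, hi = sims.min(axis=0), sims.max(axis=0)
    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(positions, lo, hi, alpha=0.25, label="simulated envelope")
    ax.plot(positions, sims.mean(axis=0), "--", lw=1, label="simulated mean")
    ax.plot(positions, r, "o", ms=3, label="|quantile residual|")
    ax.set_xlabel("half-normal quantiles")
    ax.set_ylabel("ordered |residuals|")
    ax.legend()
    return ax
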