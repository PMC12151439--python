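"""Monte-Carlo recovery studies for the NBUW distribution and regression.

Two engines:

* :func:`run_distribution_study` — repeated maximum-likelihood fits of
  NBUW(alpha, beta) on inverse-transform samples over a grid of sample
  sizes, summarized by bias, MSE and empirical 95% percentile intervals
  per parameter (default 1000 replications).
* :func:`run_regression_study` — repeated fits of the quantile regression
  under named coefficient schemes with a standard-normal covariate,
  summarized by relative percentage bias RB = 100*(mean - true)/true and
  RMSE per parameter (default 10,000 replications).

Seeding: one master seed spawns an independent SeedSequence child per
(cell, replication), so every cell is individually re-runnable and the
whole table is bit-reproducible.  Covariates are redrawn each replication
(unconditional RB/RMSE).  Replications whose optimizer fails to converge
are dropped and counted per cell.
"""

from __future__ import annotations

import warnings
import zlib

import numpy as np
import pandas as pd

from .distribution import nbuw_rvs
from .mle import _fit_arrays
from .quantreg import NBUWQuantileRegressor, simulate_regression_data

__all__ = [
    "TEXT_SCHEMES",
    "TABLE_SCHEMES",
    "run_distribution_study",
    "run_regression_study",
]

#: the five schemes as listed in the running text
TEXT_SCHEMES = {
    "scheme1": (1.3, 1.4, 2.0),
    "scheme2": (-2.0, 1.0, 1.5),
    "scheme3": (-0.2, -0.6, 2.5),
    "scheme4": (0.7, 0.4, 3.0),
    "scheme5": (1.0, 2.0, 4.0),
}

#: the four schemes as printed in the summary-table parameter columns
#: (these define the acceptance surface; the text list disagrees for the
#: last two and is exposed above for completeness)
TABLE_SCHEMES = {
    "table7-1": (1.3, 1.4, 2.0),
    "table7-2": (-2.0, 1.0, 1.5),
    "table7-3": (0.7, 0.4, 3.0),
    "table7-4": (1.0, 2.0, 4.0),
}

_DIST_N_GRID = (20, 45, 70, 95, 120, 145, 170, 195)
_REG_N_GRID = (25, 75, 150, 300)


def _cell_children(master: np.random.SeedSequence, label, replications):
    """Deterministic per-replication seed streams for one cell."""
    # zlib.crc32 is process-stable, unlike the builtin randomized hash
    key = zlib.crc32(repr(label).encode())
    cell = np.random.SeedSequence(
        entropy=master.entropy, spawn_key=(key,)
    )
    return cell.spawn(replications)


def run_distribution_study(
    alpha,
    beta,
    n_grid=_DIST_N_GRID,
    replications=1000,
    seed=0,
    level=0.95,
    failure_flag_rate=0.05,
):
    """Bias/MSE/CI table for the two-parameter MLE.

    Returns a DataFrame with one row per sample size: bias_alpha,
    bias_beta, mse_alpha, mse_beta, ci_*_lo/hi (empirical percentile
    intervals across replicate MLEs), n_failed and flagged.
    """
    if replications < 50:
        raise ValueError("need at least 50 replications for a summary")
    n_grid = tuple(int(n) for n in n_grid)
    if len(n_grid) == 0 or any(
        b <= a for a, b in zip(n_grid, n_grid[1:])
    ):
        raise ValueError("n_grid must be non-empty and strictly increasing")
    master = np.random.SeedSequence(seed)
    rows = []
    for n in n_grid:
        children = _cell_children(master, ("dist", alpha, beta, n),
                                  replications)
        estimates = np.empty((replications, 2))
        ok = np.zeros(replications, dtype=bool)
        for r, child in enumerate(children):
            x = nbuw_rvs(alpha, beta, size=n, random_state=child)
            fit = _fit_arrays(np.asarray(x))
            estimates[r] = (fit.alpha, fit.beta)
            ok[r] = fit.converged
        est = estimates[ok]
        n_failed = int((~ok).sum())
        bias = est.mean(axis=0) - np.array([alpha, beta])
        sq_err = (est - np.array([alpha, beta])) ** 2
        mse = sq_err.mean(axis=0)
        # Monte-Carlo standard error of the MSE estimate itself
        mse_se = sq_err.std(axis=0, ddof=1) / np.sqrt(len(est))
        lo = (1.0 - level) / 2.0
        qs = np.quantile(est, [lo, 1.0 - lo], axis=0)
        ci_a, ci_b = (qs[0, 0], qs[1, 0]), (qs[0, 1], qs[1, 1])
        flagged = n_failed / replications > failure_flag_rate
        if flagged:
            warnings.warn(
                f"cell n={n}: convergence failure rate "
                f"{n_failed / replications:.1%} exceeds "
                f"{failure_flag_rate:.0%}",
                stacklevel=2,
            )
        rows.append(
            {
                "n": n,
                "bias_alpha": bias[0],
                "bias_beta": bias[1],
                "mse_alpha": mse[0],
                "mse_beta": mse[1],
                "mse_alpha_se": mse_se[0],
                "mse_beta_se": mse_se[1],
                "ci_alpha_lo": ci_a[0],
                "ci_alpha_hi": ci_a[1],
                "ci_beta_lo": ci_b[0],
                "ci_beta_hi": ci_b[1],
                "n_failed": n_failed,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def run_regression_study(
    schemes=None,
    q_values=(0.1, 0.5, 0.9),
    n_grid=_REG_N_GRID,
    replications=10_000,
    seed=0,
    failure_flag_rate=0.05,
):
    """RB/RMSE table for the quantile regression MLE.

    ``schemes`` maps name -> (delta0, delta1, beta); defaults to the
    printed table schemes.  Returns a DataFrame with one row per
    (scheme, q, n): rb_delta0, rb_delta1, rb_beta (percent), rmse_* per
    parameter, n_failed, flagged.
    """
    if replications < 50:
        raise ValueError("need at least 50 replications for a summary")
    if schemes is None:
        schemes = TABLE_SCHEMES
    n_grid = tuple(int(n) for n in n_grid)
    if len(n_grid) == 0 or any(
        b <= a for a, b in zip(n_grid, n_grid[1:])
    ):
        raise ValueError("n_grid must be non-empty and strictly increasing")
    master = np.random.SeedSequence(seed)
    rows = []
    for name, (d0, d1, beta) in schemes.items():
        truth = np.array([d0, d1, beta])
        for q in q_values:
            for n in n_grid:
                children = _cell_children(
                    master, ("reg", name, q, n), replications
                )
                estimates = np.empty((replications, 3))
                ok = np.zeros(replications, dtype=bool)
                model = NBUWQuantileRegressor(q=q)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    for r, child in enumerate(children):
                        X, y = simulate_regression_data(
                            (d0, d1), beta, q, n, seed=child
                        )
                        try:
                            model.fit(X, y)
                        except (ValueError, np.linalg.LinAlgError):
                            continue
                        estimates[r] = (
                            model.intercept_,
                            model.coef_[0],
                            model.shape_,
                        )
                        ok[r] = model.converged_
                est = estimates[ok]
                n_failed = int((~ok).sum())
                rb = 100.0 * (est.mean(axis=0) - truth) / truth
                rb_se = (
                    100.0 * est.std(axis=0, ddof=1)
                    / (np.sqrt(len(est)) * np.abs(truth))
                )
                sq_err = (est - truth) ** 2
                rmse = np.sqrt(sq_err.mean(axis=0))
                # delta-method MC standard error of the RMSE estimate
                rmse_se = (
                    sq_err.std(axis=0, ddof=1)
                    / (2.0 * rmse * np.sqrt(len(est)))
                )
                flagged = n_failed / replications > failure_flag_rate
                if flagged:
                    warnings.warn(
                        f"cell ({name}, q={q}, n={n}): failure rate "
                        f"{n_failed / replications:.1%}",
                        stacklevel=2,
                    )
                rows.append(
                    {
                        "scheme": name,
                        "delta0": d0,
                        "delta1": d1,
                        "beta": beta,
                        "q": q,
                        "n": n,
                        "rb_delta0": rb[0],
                        "rb_delta1": rb[1],
                        "rb_beta": rb[2],
                        "rmse_delta0": rmse[0],
                        "rmse_delta1": rmse[1],
                        "rmse_beta": rmse[2],
                        # shape RMSE on the relative scale (RMSE/beta),
                        # the scale the published summary tables print
                        "rel_rmse_beta": rmse[2] / beta,
                        "rmse_delta0_se": rmse_se[0],
                        "rmse_delta1_se": rmse_se[1],
                        "rmse_beta_se": rmse_se[2],
                        "rb_delta0_se": rb_se[0],
                        "rb_delta1_se": rb_se[1],
                        "n_failed": n_failed,
                        "flagged": flagged,
                    }
                )
    return pd.DataFrame(rows)
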