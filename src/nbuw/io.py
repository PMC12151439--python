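"""Tabular I/O and report writing for the command-line tools.

Plain CSV/TSV in, JSON/TSV out.  ``read_regression_table`` validates the
response against the (0, 1] support with the same clamping policy as the
likelihood code (exact ones clamped with a warning, zeros rejected with
their row indices).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .mle import prepare_unit_data

__all__ = ["RegressionTable", "read_regression_table", "write_json_report"]


@dataclass
class RegressionTable:
    """Validated regression inputs: design (with intercept) and response."""

    design: np.ndarray
    response: np.ndarray
    covariate_names: list[str]
    response_name: str
    n_dropped: int = 0
    n_clamped: int = 0

    @property
    def covariates(self) -> np.ndarray:
        """Design without the leading intercept column."""
        return self.design[:, 1:]


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def read_regression_table(path, response_column, covariate_columns):
    """Load a CSV/TSV into a validated :class:`RegressionTable`.

    Rows with missing values in the used columns are dropped (and
    counted); a response of exactly 0 or outside (0, 1] is an error that
    names the offending rows; responses exactly 1 are clamped per the
    boundary policy.
    """
    df = _read_delimited(path)
    cols = [response_column, *covariate_columns]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"columns {missing} not found; file has {list(df.columns)}"
        )
    sub = df[cols].apply(pd.to_numeric, errors="coerce")
    non_numeric = sub.columns[sub.isna().all()].tolist()
    if non_numeric:
        raise ValueError(f"columns {non_numeric} are entirely non-numeric")
    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    sub = sub[keep]
    if sub.empty:
        raise ValueError("no rows left after dropping missing values")
    y_raw = sub[response_column].to_numpy(dtype=float)
    bad = np.flatnonzero((y_raw <= 0) | (y_raw > 1))
    if bad.size:
        rows = sub.index[bad][:10].tolist()
        raise ValueError(
            f"response {response_column!r} outside (0, 1] in rows {rows}"
        )
    y, n_clamped = prepare_unit_data(y_raw)
    X = sub[list(covariate_columns)].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(y)), X])
    return RegressionTable(
        design=design,
        response=y,
        covariate_names=list(covariate_columns),
        response_name=response_column,
        n_dropped=n_dropped,
        n_clamped=n_clamped,
    )


def run_metadata(config: dict) -> dict:
    """Version/seed/timestamp block embedded in every report."""
    try:
        pkg_version = version("nbuw")
    except PackageNotFoundError:
        pkg_version = "unknown"
    return {
        "tool": "nbuw",
        "version": pkg_version,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
    }


def write_json_report(path, payload: dict, config: dict | None = None):
    payload = dict(payload)
    payload["metadata"] = run_metadata(config or {})
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
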