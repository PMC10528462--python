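"""Long-format CSV ingest and JSON fit serialization.

Functional covariates are 4-dimensional (subject, covariate, t, s), so the
on-disk format is an unambiguous long table:

* responses: columns ``subject_id, t, y`` — every (subject, t) pair present;
* covariates: columns ``subject_id, j, t, s, x`` with ``j`` the 1-based
  covariate index — every (subject, j, t, s) cell present.

Grids are the sorted unique values; ingest is row-order invariant and
reports the first missing cell by name.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import FunctionalDataset
from .solver import FitResult

__all__ = ["read_dataset", "write_fit", "read_fit"]

FIT_FORMAT_VERSION = 1

_RESP_COLS = ["subject_id", "t", "y"]
_COV_COLS = ["subject_id", "j", "t", "s", "x"]


def _check_columns(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns {missing}")
    for c in cols:
        if c != "subject_id" and not np.issubdtype(df[c].dtype, np.number):
            raise ValueError(f"{what} column {c!r} is not numeric")
        if df[c].isna().any():
            raise ValueError(f"{what} column {c!r} contains missing values")


def read_dataset(
    response_path: str | Path | None, covariate_path: str | Path
) -> FunctionalDataset:
    """Read long-format CSVs into a validated :class:`FunctionalDataset`.

    ``response_path`` may be None for prediction-only covariate data.
    """
    cov = pd.read_csv(covariate_path)
    _check_columns(cov, _COV_COLS, "covariate")
    subjects = sorted(cov["subject_id"].unique())
    js = sorted(cov["j"].unique())
    t_grid = np.sort(cov["t"].unique())
    s_grid = np.sort(cov["s"].unique())
    if list(js) != list(range(1, len(js) + 1)):
        raise ValueError(f"covariate indices j must be 1..q, found {js}")
    n, q = len(subjects), len(js)
    sub_pos = {s: i for i, s in enumerate(subjects)}
    t_pos = {v: i for i, v in enumerate(t_grid)}
    s_pos = {v: i for i, v in enumerate(s_grid)}

    x = np.full((n, q, t_grid.size, s_grid.size), np.nan)
    ii = cov["subject_id"].map(sub_pos).to_numpy()
    jj = cov["j"].to_numpy(dtype=int) - 1
    tt = cov["t"].map(t_pos).to_numpy()
    ss = cov["s"].map(s_pos).to_numpy()
    x[ii, jj, tt, ss] = cov["x"].to_numpy(dtype=float)
    if np.isnan(x).any():
        i, j, a, b = np.argwhere(np.isnan(x))[0]
        raise ValueError(
            f"missing covariate cell: subject_id={subjects[i]}, j={j + 1}, "
            f"t={t_grid[a]}, s={s_grid[b]}"
        )

    y = None
    if response_path is not None:
        resp = pd.read_csv(response_path)
        _check_columns(resp, _RESP_COLS, "response")
        if sorted(resp["subject_id"].unique()) != subjects:
            raise ValueError("response and covariate tables list different subjects")
        rt = np.sort(resp["t"].unique())
        if rt.size != t_grid.size or not np.allclose(rt, t_grid):
            raise ValueError("response t-grid differs from covariate t-grid")
        y = np.full((n, t_grid.size), np.nan)
        ii = resp["subject_id"].map(sub_pos).to_numpy()
        tt = resp["t"].map(t_pos).to_numpy()
        y[ii, tt] = resp["y"].to_numpy(dtype=float)
        if np.isnan(y).any():
            i, a = np.argwhere(np.isnan(y))[0]
            raise ValueError(
                f"missing response cell: subject_id={subjects[i]}, t={t_grid[a]}"
            )
    return FunctionalDataset(t_grid, s_grid, x, y)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_fit(fit: FitResult, path: str | Path) -> None:
    """Serialize a fit to JSON, preserving coefficients to full precision."""
    payload = {
        "format_version": FIT_FORMAT_VERSION,
        "method": fit.method,
        "scheme_id": fit.scheme_id,
        "d": fit.d.tolist(),
        "c": fit.c.tolist(),
        "theta": fit.theta.tolist(),
        "labels": list(fit.labels),
        "selected": list(fit.selected),
        "tuning": _jsonify(fit.tuning),
        "trace": [float(v) for v in fit.trace],
        "converged": bool(fit.converged),
        "n": int(fit.n),
        "K": int(fit.K),
        "seed": fit.seed,
    }
    Path(path).write_text(json.dumps(payload))


def read_fit(path: str | Path) -> FitResult:
    """Load a JSON fit written by :func:`write_fit`."""
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != FIT_FORMAT_VERSION:
        raise ValueError(
            f"unsupported fit file version {version!r} (expected {FIT_FORMAT_VERSION})"
        )
    return FitResult(
        d=np.asarray(payload["d"], float),
        c=np.asarray(payload["c"], float),
        theta=np.asarray(payload["theta"], float),
        tuning=payload["tuning"],
        selected=[int(v) for v in payload["selected"]],
        labels=list(payload["labels"]),
        trace=[float(v) for v in payload["trace"]],
        converged=bool(payload["converged"]),
        method=payload["method"],
        scheme_id=payload["scheme_id"],
        n=int(payload["n"]),
        K=int(payload["K"]),
        seed=payload["seed"],
    )
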