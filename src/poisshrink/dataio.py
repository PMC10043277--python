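"""Dataset readers/writers and fixture generators.

Count datasets are plain delimited text with a header; the response column is
named by the caller and must hold non-negative integers (no imputation —
missing values are rejected).  Fixture generators produce small deterministic
datasets so the whole package is exercisable without any download.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .glm_core import CountDataset
from .simulation import generate_design, true_beta

__all__ = ["read_count_csv", "write_count_csv", "generate_fixture"]


def read_count_csv(path: str | Path, response_column: str, sep: str = ",") -> CountDataset:
    """Read a delimited text file into a validated :class:`CountDataset`."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path}: file has no data rows")
    if response_column not in df.columns:
        raise ValueError(
            f"{path}: response column {response_column!r} not found "
            f"(columns: {list(df.columns)})"
        )
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"{path}: missing values in column(s) {bad}; no imputation is done")
    y = df[response_column]
    frac = y - np.round(y)
    if np.any(y < 0) or np.any(np.abs(frac) > 1e-9):
        bad_rows = df.index[(y < 0) | (np.abs(frac) > 1e-9)].tolist()
        raise ValueError(
            f"{path}: response column {response_column!r} must be non-negative "
            f"integers; offending row(s) {bad_rows}"
        )
    covars = df.drop(columns=[response_column])
    for col in covars.columns:
        if not np.issubdtype(covars[col].dtype, np.number):
            raise ValueError(f"{path}: covariate column {col!r} is not numeric")
    return CountDataset(
        design=covars.to_numpy(dtype=float),
        response=y.to_numpy(),
        include_intercept=False,
        standardized=False,
        column_names=list(covars.columns),
    )


def write_count_csv(dataset: CountDataset, path: str | Path, response_name: str = "y") -> None:
    if dataset.response is None:
        raise ValueError("dataset has no response to write")
    cols = dataset.column_names
    start = 1 if dataset.include_intercept else 0
    df = pd.DataFrame(dataset.design[:, start:], columns=cols[start:])
    df[response_name] = dataset.response.astype(int)
    df.to_csv(path, index=False)


def _aircraft_like(rng: np.random.Generator) -> CountDataset:
    """A synthetic stand-in mimicking the shape of the classic aircraft-damage
    data: n=30, one binary covariate (aircraft type), bomb load in tons, and
    aircrew experience in months, with Poisson counts from a fitted-scale
    linear predictor.  Synthetic — generated here, not the published dataset."""
    n = 30
    x1 = (np.arange(n) >= n // 2).astype(float)
    x2 = np.round(rng.uniform(4.0, 14.0, size=n), 1)
    x3 = np.round(rng.uniform(50.0, 120.0, size=n), 1)
    # collinearity: heavier loads tend to pair with one aircraft type
    x2 = np.round(x2 + 2.5 * x1, 1)
    eta = -1.0 + 0.6 * x1 + 0.17 * x2 - 0.012 * x3
    y = rng.poisson(np.exp(eta))
    return CountDataset(
        design=np.column_stack([x1, x2, x3]),
        response=y,
        column_names=["type", "bomb_load", "experience"],
    )


def _collinear_toy(rng: np.random.Generator, n: int = 40, p: int = 3, rho: float = 0.99) -> CountDataset:
    design = generate_design(n, p, rho, rng, standardize_design=True)
    beta = true_beta(design)
    y = rng.poisson(np.exp(design.design @ beta))
    return design.with_response(y)


def generate_fixture(kind: str, seed: int = 0, path: str | Path | None = None) -> CountDataset:
    """Deterministic-for-seed toy datasets: ``aircraft_like`` (raw covariates,
    standardize before fitting) or ``collinear_toy`` (standardized columns,
    high collinearity, no intercept)."""
    rng = np.random.default_rng(seed)
    if kind == "aircraft_like":
        data = _aircraft_like(rng)
    elif kind == "collinear_toy":
        data = _collinear_toy(rng)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; use aircraft_like or collinear_toy")
    if path is not None:
        write_count_csv(data, path)
    return data
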