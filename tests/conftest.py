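"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from limnoqe.io import MonitoringRecord, MonthlySeries


def ols_normal_equations(x: np.ndarray, y: np.ndarray):
    """Closed-form simple-regression solution from the normal equations.

    Independent of any library fitting routine: slope and intercept from the
    textbook sums, Pearson r from the covariance identity, residual standard
    error with an n-2 denominator.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy, syy = (x * x).sum(), (x * y).sum(), (y * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - slope * x - intercept
    se = np.sqrt((resid * resid).sum() / (n - 2))
    denom = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    r = (n * sxy - sx * sy) / denom if denom > 0 else 0.0
    return slope, intercept, r, se


def ols_multi_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Multiple-regression coefficients via the normal equations (X'X)b = X'y."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def make_monthly_series(
    reservoir: str = "Testwater",
    start: str = "2000-01",
    **columns,
) -> MonthlySeries:
    """Assemble a MonthlySeries from equal-length column arrays."""
    n = len(next(iter(columns.values())))
    index = pd.period_range(start, periods=n, freq="M")
    frame = pd.DataFrame(
        {c: np.asarray(columns.get(c, np.full(n, np.nan)), float)
         for c in ("chl", "tp", "sd", "d_cyano", "volume")},
        index=index,
    )
    return MonthlySeries(reservoir, frame)


@pytest.fixture
def rng():
    return np.random.default_rng(20240422)


@pytest.fixture(scope="session")
def flumendosa_series():
    """One default 204-month synthetic campaign, shared across tests."""
    from limnoqe.synth import default_config, generate_monitoring

    return generate_monitoring(default_config("Flumendosa", seed=7))


@pytest.fixture
def three_records():
    return [
        MonitoringRecord("Mulargia", "2005-06", depth=0.5, chl=4.0, tp=20.0,
                         sd=2.0, d_cyano=5e5, volume=150.0),
        MonitoringRecord("Mulargia", "2005-06", depth=1.0, chl=6.0),
        MonitoringRecord("Mulargia", "2005-07", chl=3.0, tp=18.0),
    ]
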