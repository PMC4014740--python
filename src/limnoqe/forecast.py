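"""Autoregressive forecasting of TSI and cyanobacteria density.

Both state variables follow a lag-1 multiple linear regression on stored
volume and a seasonal time term,

    x_t = a * x_{t-1} + b * V_t + c . T_t + d + eps_t,

where x is either the monthly TSI or the natural log of cyanobacteria
density, V_t the stored volume (10^6 m^3), and T_t a seasonal encoding of the
calendar month (harmonic sin/cos pair by default, 11 month indicators
optionally).  Chaining the two fitted models with the QE rule produces the
monthly quality scenario series consumed by reservoir-system optimization.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    DegenerateDesignError,
    DomainError,
    InsufficientDataError,
    UsageError,
)
from .io import MonthlySeries
from .trophic import (
    POTABLE_DENSITY_THRESHOLD,
    SiteTsiModel,
    qe_index,
    tsi_from_chl,
    tsi_from_sd,
    tsi_from_tp,
)

logger = logging.getLogger(__name__)

HARMONIC = "harmonic"
MONTH_INDICATOR = "month"

#: density floor (cells/L) applied before the log transform
DENSITY_FLOOR = 1e3

#: minimum usable months required to fit
MIN_FIT_MONTHS = 24

_TSI_FUNCS = {"chl": tsi_from_chl, "tp": tsi_from_tp, "sd": tsi_from_sd}


def encode_time(month, encoding: str = HARMONIC) -> np.ndarray:
    """Seasonal covariate vector(s) for calendar month(s) 1..12.

    ``harmonic``: (sin, cos) of 2*pi*month/12.  ``month``: 11 indicator
    columns for February..December (January is the reference level, absorbed
    by the intercept).
    """
    m = np.atleast_1d(np.asarray(month, dtype=int))
    if np.any((m < 1) | (m > 12)):
        raise UsageError("month must be in 1..12")
    if encoding == HARMONIC:
        angle = 2.0 * np.pi * m / 12.0
        out = np.column_stack([np.sin(angle), np.cos(angle)])
    elif encoding == MONTH_INDICATOR:
        out = np.zeros((m.size, 11))
        for i, mm in enumerate(m):
            if mm >= 2:
                out[i, mm - 2] = 1.0
    else:
        raise UsageError(f"unknown seasonal encoding {encoding!r}")
    return out[0] if np.isscalar(month) else out


@dataclass
class ArModel:
    """Fitted lag-1 volume/season regression for one state variable."""

    target: str  # "tsi" or "ln_cyano"
    a: float
    b: float
    c: np.ndarray
    d: float
    r: float
    se: float
    n: int
    time_encoding: str = HARMONIC
    #: standard errors aligned with (a, b, *c, d)
    param_se: Optional[np.ndarray] = None
    floored_months: int = 0

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.a, self.b], np.asarray(self.c), [self.d]])

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Normal-approximation (1-alpha) confidence intervals per parameter."""
        from scipy import stats

        if self.param_se is None:
            raise UsageError("model has no stored parameter standard errors")
        k = self.params.size
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, self.n - k)
        half = tcrit * self.param_se
        return np.column_stack([self.params - half, self.params + half])

    def to_json(self, path) -> None:
        payload = {
            "target": self.target,
            "a": self.a,
            "b": self.b,
            "c": list(np.asarray(self.c)),
            "d": self.d,
            "r": self.r,
            "se": self.se,
            "n": self.n,
            "time_encoding": self.time_encoding,
            "param_se": None if self.param_se is None else list(self.param_se),
            "floored_months": self.floored_months,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "ArModel":
        raw = json.loads(Path(path).read_text())
        raw["c"] = np.asarray(raw["c"], dtype=float)
        if raw.get("param_se") is not None:
            raw["param_se"] = np.asarray(raw["param_se"], dtype=float)
        return cls(**raw)


@dataclass
class ScenarioSeries:
    """Predicted monthly volume/TSI/density/QE table for one reservoir."""

    reservoir: str
    frame: pd.DataFrame  # columns: volume, tsi, d_cyano, qe

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "reservoir", self.reservoir)
        out.index.name = "date"
        out = out.rename(
            columns={"volume": "volume_Mm3", "d_cyano": "d_cyano_cells_L"}
        )
        out.to_csv(path, date_format="%Y-%m")


def _target_series(
    series: MonthlySeries,
    target: str,
    tsi_variant: str,
    site: SiteTsiModel,
    density_floor: float,
) -> tuple[pd.Series, int]:
    frame = series.frame
    floored = 0
    if target == "tsi":
        if tsi_variant not in _TSI_FUNCS:
            raise UsageError(f"unknown tsi_variant {tsi_variant!r}")
        col = {"chl": "chl", "tp": "tp", "sd": "sd"}[tsi_variant]
        values = frame[col].to_numpy(dtype=float)
        out = np.full(values.shape, np.nan)
        ok = np.isfinite(values) & (values > 0)
        if ok.any():
            out[ok] = _TSI_FUNCS[tsi_variant](values[ok], site)
        y = pd.Series(out, index=frame.index)
    elif target == "ln_cyano":
        dens = frame["d_cyano"].to_numpy(dtype=float)
        out = np.full(dens.shape, np.nan)
        ok = np.isfinite(dens)
        floored = int(np.sum(ok & (dens < density_floor)))
        if floored:
            logger.info("ln_cyano: %d month(s) floored at %g cells/L", floored, density_floor)
        out[ok] = np.log(np.maximum(dens[ok], density_floor))
        y = pd.Series(out, index=frame.index)
    else:
        raise UsageError(f"unknown target {target!r} (use 'tsi' or 'ln_cyano')")
    return y, floored


def fit_ar(
    series: MonthlySeries,
    target: str = "tsi",
    tsi_variant: str = "chl",
    encoding: str = HARMONIC,
    site: SiteTsiModel = SiteTsiModel(),
    density_floor: float = DENSITY_FLOOR,
    min_months: int = MIN_FIT_MONTHS,
) -> ArModel:
    """Fit the lag-1 volume/season regression by OLS.

    Usable rows require the target at t and t-1 in consecutive calendar
    months plus the stored volume at t; months following a gap are excluded.
    """
    y, floored = _target_series(series, target, tsi_variant, site, density_floor)
    frame = series.frame
    # reindex to a gap-free monthly range so positional lagging is calendar lagging
    full = pd.period_range(frame.index.min(), frame.index.max(), freq="M")
    y = y.reindex(full)
    vol = frame["volume"].reindex(full).to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    y_now, y_lag = yv[1:], yv[:-1]
    v_now = vol[1:]
    months = full.month.to_numpy()[1:]
    T = np.atleast_2d(encode_time(months, encoding))
    ok = np.isfinite(y_now) & np.isfinite(y_lag) & np.isfinite(v_now)
    n = int(ok.sum())
    k = 3 + T.shape[1]
    if n < max(min_months, k + 1):
        raise InsufficientDataError(
            f"only {n} usable month(s); need >= {max(min_months, k + 1)}"
        )
    X = np.column_stack([y_lag[ok], v_now[ok], T[ok], np.ones(n)])
    if np.linalg.matrix_rank(X) < X.shape[1] or np.ptp(y_now[ok]) == 0:
        raise DegenerateDesignError(
            "degenerate design (constant target or collinear regressors)"
        )
    res = sm.OLS(y_now[ok], X).fit()
    resid = res.resid
    se = math.sqrt(float(resid @ resid) / (n - X.shape[1]))
    r = math.sqrt(max(float(res.rsquared), 0.0))
    params = np.asarray(res.params, dtype=float)
    return ArModel(
        target=target,
        a=float(params[0]),
        b=float(params[1]),
        c=params[2:-1].copy(),
        d=float(params[-1]),
        r=r,
        se=se,
        n=n,
        time_encoding=encoding,
        param_se=np.asarray(res.bse, dtype=float),
        floored_months=floored,
    )


def predict_series(
    model: ArModel,
    initial_value: float,
    volumes: Sequence[float],
    months: Sequence[int],
) -> np.ndarray:
    """Recursive one-step forecasts over the given volume/month path.

    ``initial_value`` is in natural units (TSI, or cells/L for the density
    model); density forecasts are exponentiated back to cells/L.
    """
    vols = np.asarray(volumes, dtype=float)
    mons = np.asarray(months, dtype=int)
    if vols.shape != mons.shape or vols.ndim != 1 or vols.size < 1:
        raise UsageError("volumes and months must be 1-d sequences of equal length >= 1")
    if not np.isfinite(initial_value):
        raise DomainError("initial value must be finite")
    x = float(initial_value)
    if model.target == "ln_cyano":
        if x <= 0:
            raise DomainError("initial density must be > 0 cells/L")
        x = math.log(x)
    T = np.atleast_2d(encode_time(mons, model.time_encoding))
    c = np.asarray(model.c, dtype=float)
    out = np.empty(vols.size)
    for t in range(vols.size):
        x = model.a * x + model.b * vols[t] + float(c @ T[t]) + model.d
        out[t] = x
    if model.target == "ln_cyano":
        out = np.exp(out)
    return out


def qe_scenario(
    tsi_model: ArModel,
    cyano_model: ArModel,
    initial_tsi: float,
    initial_density: float,
    volumes: Sequence[float],
    months: Sequence[int],
    threshold: float = POTABLE_DENSITY_THRESHOLD,
    reservoir: str = "",
    start: Optional[str] = None,
) -> ScenarioSeries:
    """Forecast TSI and cyanobacteria density and classify each month's QE."""
    if tsi_model.target != "tsi" or cyano_model.target != "ln_cyano":
        raise UsageError("expected a 'tsi' model and a 'ln_cyano' model")
    tsi = predict_series(tsi_model, initial_tsi, volumes, months)
    dens = predict_series(cyano_model, initial_density, volumes, months)
    qe = np.asarray(qe_index(tsi, dens, threshold))
    if start is not None:
        index = pd.period_range(start, periods=len(tsi), freq="M")
    else:
        index = pd.RangeIndex(len(tsi))
    frame = pd.DataFrame(
        {
            "volume": np.asarray(volumes, dtype=float),
            "tsi": tsi,
            "d_cyano": dens,
            "qe": qe.astype(int),
        },
        index=index,
    )
    return ScenarioSeries(reservoir=reservoir, frame=frame)
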