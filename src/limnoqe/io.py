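"""Monitoring-data model, CSV round-trip, and temporal aggregation.

The atom of the package is a single limnological sampling observation
(:class:`MonitoringRecord`).  Raw observations are aggregated to a monthly
surface series (:class:`MonthlySeries`) and paired across seasons into the
spring-phosphorus / summer-chlorophyll calibration pairs used by the
log-linear nutrient--biomass regressions.

CSV dialect
-----------
``reservoir,date,depth_m,chl_mg_m3,tp_ug_L,sd_m,d_cyano_cells_L,volume_Mm3``
UTF-8, "." decimal separator, empty string = missing.  Units are fixed:
Chl-a in mg/m^3, total phosphorus in ug/L, Secchi depth in m, cyanobacteria
density in cells/L, stored volume in 10^6 m^3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError, ValidationError

logger = logging.getLogger(__name__)

#: canonical CSV header -> record attribute
CSV_COLUMNS = {
    "reservoir": "reservoir",
    "date": "date",
    "depth_m": "depth",
    "chl_mg_m3": "chl",
    "tp_ug_L": "tp",
    "sd_m": "sd",
    "d_cyano_cells_L": "d_cyano",
    "volume_Mm3": "volume",
}

#: aggregated value columns of a MonthlySeries frame
VALUE_COLUMNS = ("chl", "tp", "sd", "d_cyano", "volume")

#: default maximum sampling depth treated as "surface" (m)
SURFACE_DEPTH_MAX = 2.5

SPRING_MONTHS = frozenset({3, 4})
SUMMER_MONTHS = frozenset({6, 7, 8})


@dataclass
class MonitoringRecord:
    """One sampling observation at a reservoir station.

    ``date`` is an ISO year-month string (``"YYYY-MM"``); all other fields
    except ``reservoir`` are optional and ``None`` when not measured.
    """

    reservoir: str
    date: str
    depth: Optional[float] = None
    chl: Optional[float] = None
    tp: Optional[float] = None
    sd: Optional[float] = None
    d_cyano: Optional[float] = None
    volume: Optional[float] = None

    def validate(self) -> None:
        if not self.reservoir:
            raise ValidationError("reservoir identifier is empty")
        try:
            pd.Period(self.date, freq="M")
        except Exception as exc:  # noqa: BLE001 - pandas raises several types
            raise ValidationError(f"date {self.date!r} is not a valid year-month") from exc
        for name in ("depth", "chl", "tp", "d_cyano", "volume"):
            value = getattr(self, name)
            if value is not None and (not np.isfinite(value) or value < 0):
                raise ValidationError(f"{name}={value} must be finite and >= 0")
        if self.sd is not None and (not np.isfinite(self.sd) or self.sd <= 0):
            raise ValidationError(f"sd={self.sd} must be finite and > 0")

    @property
    def period(self) -> pd.Period:
        return pd.Period(self.date, freq="M")


@dataclass
class MonthlySeries:
    """Month-indexed surface means for one reservoir.

    ``frame`` is indexed by a monthly :class:`pandas.PeriodIndex` spanning the
    observed range without holes; a ``NaN`` cell marks a month with no usable
    sample for that field (a gap).
    """

    reservoir: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.frame.index, pd.PeriodIndex):
            raise UsageError("MonthlySeries.frame must be indexed by a monthly PeriodIndex")
        if not self.frame.index.is_monotonic_increasing or self.frame.index.has_duplicates:
            raise UsageError("month index must be strictly increasing")

    @property
    def months(self) -> pd.PeriodIndex:
        return self.frame.index

    def gap_months(self, field: str) -> pd.PeriodIndex:
        """Months flagged as gaps (no usable sample) for ``field``."""
        return self.frame.index[self.frame[field].isna()]


@dataclass
class CalibrationPair:
    """Spring-overturn TP paired with the same year's summer mean Chl-a."""

    reservoir: str
    year: int
    tp_spring: float
    chl_summer: float

    def __post_init__(self) -> None:
        if not (self.tp_spring > 0 and self.chl_summer > 0):
            raise ValidationError(
                f"calibration pair for {self.reservoir} {self.year} needs positive "
                f"TP and Chl (got {self.tp_spring}, {self.chl_summer})"
            )


def read_monitoring(path) -> list[MonitoringRecord]:
    """Read a monitoring CSV into validated records, preserving row order."""
    table = pd.read_csv(path, dtype=str, skipinitialspace=True)
    table.columns = [c.strip() for c in table.columns]
    lower = {c.lower(): c for c in table.columns}
    missing = [c for c in ("reservoir", "date") if c not in lower]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[MonitoringRecord] = []
    for i, (_, row) in enumerate(table.iterrows(), start=1):
        kwargs = {}
        for col, attr in CSV_COLUMNS.items():
            if col.lower() not in lower:
                continue
            raw = row[lower[col.lower()]]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                continue
            if attr in ("reservoir", "date"):
                kwargs[attr] = str(raw).strip()
            else:
                try:
                    kwargs[attr] = float(raw)
                except ValueError as exc:
                    raise FormatError(f"row {i}: cannot parse {col}={raw!r} as a number") from exc
        if "reservoir" not in kwargs or "date" not in kwargs:
            raise FormatError(f"row {i}: reservoir and date are mandatory")
        record = MonitoringRecord(**kwargs)
        try:
            record.validate()
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        records.append(record)
    return records


def write_monitoring(records: Iterable[MonitoringRecord], path) -> None:
    """Write records to the documented CSV dialect (inverse of read_monitoring)."""
    rows = []
    for record in records:
        rows.append({col: getattr(record, attr) for col, attr in CSV_COLUMNS.items()})
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    frame.to_csv(path, index=False)


def monthly_aggregate(
    records: Sequence[MonitoringRecord],
    surface_depth_max: float = SURFACE_DEPTH_MAX,
) -> MonthlySeries:
    """Collapse raw samples to monthly surface means.

    Per month and field, the arithmetic mean over samples taken at depth
    <= ``surface_depth_max`` (samples without a recorded depth count as
    surface).  Months inside the observed range with no usable sample for a
    field are flagged as gaps (NaN).
    """
    if not records:
        raise UsageError("no records to aggregate")
    reservoirs = {r.reservoir for r in records}
    if len(reservoirs) != 1:
        raise UsageError(f"records mix reservoirs: {sorted(reservoirs)}")
    reservoir = reservoirs.pop()

    rows = []
    for record in records:
        if record.depth is not None and record.depth > surface_depth_max:
            continue
        rows.append(
            {
                "period": record.period,
                **{f: getattr(record, f) for f in VALUE_COLUMNS},
            }
        )
    periods = pd.PeriodIndex([r.period for r in records], freq="M")
    full = pd.period_range(periods.min(), periods.max(), freq="M")
    if not rows:
        frame = pd.DataFrame(np.nan, index=full, columns=list(VALUE_COLUMNS))
        return MonthlySeries(reservoir, frame)
    raw = pd.DataFrame(rows)
    grouped = raw.groupby("period")[list(VALUE_COLUMNS)].mean()
    frame = grouped.reindex(full)
    return MonthlySeries(reservoir, frame)


def pair_spring_summer(
    series: MonthlySeries,
    spring_months: Iterable[int] = SPRING_MONTHS,
    summer_months: Iterable[int] = SUMMER_MONTHS,
) -> list[CalibrationPair]:
    """Build per-year (spring TP, summer Chl) calibration pairs.

    Spring TP is the mean of monthly TP over the spring-overturn months of a
    year; summer Chl the mean of monthly Chl over the summer months.  Years
    missing either side are skipped (logged at INFO).
    """
    spring = frozenset(spring_months)
    summer = frozenset(summer_months)
    if not spring or not summer:
        raise UsageError("spring and summer month sets must be non-empty")
    bad = {m for m in spring | summer if m not in range(1, 13)}
    if bad:
        raise UsageError(f"invalid month number(s): {sorted(bad)}")

    frame = series.frame
    month_of = frame.index.month
    year_of = frame.index.year
    pairs: list[CalibrationPair] = []
    for year in np.unique(year_of):
        in_year = year_of == year
        tp = frame.loc[in_year & np.isin(month_of, list(spring)), "tp"].dropna()
        chl = frame.loc[in_year & np.isin(month_of, list(summer)), "chl"].dropna()
        if tp.empty or chl.empty:
            logger.info(
                "pair_spring_summer: %s %d skipped (spring TP n=%d, summer Chl n=%d)",
                series.reservoir, year, len(tp), len(chl),
            )
            continue
        tp_mean = float(tp.mean())
        chl_mean = float(chl.mean())
        if tp_mean <= 0 or chl_mean <= 0:
            logger.info(
                "pair_spring_summer: %s %d skipped (non-positive mean)", series.reservoir, year
            )
            continue
        pairs.append(CalibrationPair(series.reservoir, int(year), tp_mean, chl_mean))
    return pairs
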