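"""Phytoplankton composition, cyanobacteria bloom flagging, and microcystin
screening against the WHO drinking-water guideline.

Composition processing follows the standard three-step survey procedure:
per-class mean annual densities (absolute and percent of total), per-class
minimum and maximum over the study period, and the most representative
species of each class.  Cyanobacteria are considered blooming when their
summed cell count exceeds one million cells per liter.  Microcystin samples
carry intracellular (cell-bound) and extracellular (dissolved) fractions;
totals are recomputed as in + ex and checked against the stored value, and
screening compares concentrations with the WHO guideline of 1 ug/L for total
microcystin-LR in drinking water.  ELISA plate assays are only valid in the
0-5 ppb range, so values reported as ">5.0" are right-censored at the bound.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

#: cyanobacteria density above which a reservoir-month counts as a bloom (cells/L)
BLOOM_THRESHOLD = 1e6

#: WHO provisional guideline for total microcystin-LR in drinking water (ug/L)
WHO_MCYST_GUIDELINE = 1.0

#: |in + ex - stored total| above this is an inconsistency rather than
#: rounding of values printed to one decimal (half an ulp per addend)
MCYST_CONSISTENCY_TOL = 0.05

ALGAL_CLASSES = (
    "Cyanobacteria",
    "Chlorophyceae",
    "Bacillariophyceae",
    "Cryptophyceae",
    "Conjugatophyceae",
    "Other",
)

#: static cyanotoxin -> producer-genus reference (annotation only)
TOXIN_PRODUCERS = {
    "anatoxin-a": ("Anabaena", "Aphanizomenon"),
    "homo-anatoxin-a": ("Oscillatoria (Planktothrix)",),
    "anatoxin-a(s)": ("Anabaena", "Oscillatoria (Planktothrix)"),
    "saxitoxins": ("Anabaena", "Aphanizomenon"),
    "cylindrospermopsin": ("Aphanizomenon", "Cylindrospermopsis"),
    "microcystins": ("Anabaena", "Aphanocapsa", "Microcystis", "Oscillatoria (Planktothrix)"),
    "nodularins": ("Nodularia",),
    "aplysiatoxin": ("Schizothrix",),
}


@dataclass
class PhytoRecord:
    """One species-level density observation (cells/L)."""

    reservoir: str
    date: str
    algal_class: str
    species: str
    density: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.density) or self.density < 0:
            raise ValidationError(f"density={self.density} must be finite and >= 0")


@dataclass
class AnnualClassSummary:
    """Per-class composition of one reservoir-year."""

    reservoir: str
    year: int
    class_mean: dict  # class -> mean monthly density (cells/L)
    class_percent: dict  # class -> percent of the year's total
    class_min: dict  # class -> study-period minimum of monthly density
    class_max: dict  # class -> study-period maximum
    top_species: dict  # class -> most representative species (by mean density)


@dataclass
class ToxinSample:
    """Microcystin fractions at one station/depth; censored values at bound."""

    reservoir: str
    date: str
    depth: float
    density: float  # 10^6 cells/L
    mcyst_in: Optional[float] = None
    mcyst_ex: Optional[float] = None
    mcyst_tot: Optional[float] = None
    censored_in: bool = False
    censored_ex: bool = False
    censored_tot: bool = False


@dataclass
class McystTotal:
    value: float
    censored: bool
    inconsistent: Optional[bool]  # None when no stored total to compare


@dataclass
class ScreeningReport:
    table: pd.DataFrame
    max_extracellular: Optional[float]
    max_total_noncensored: Optional[float]
    n_extracellular_exceeding: int
    n_total_exceeding: int
    n_inconsistent: int
    guideline: float = WHO_MCYST_GUIDELINE


def _records_frame(records: Sequence[PhytoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "reservoir": [r.reservoir for r in records],
            "period": pd.PeriodIndex([r.date for r in records], freq="M"),
            "algal_class": [r.algal_class for r in records],
            "species": [r.species for r in records],
            "density": [r.density for r in records],
        }
    )


def annual_class_summary(records: Sequence[PhytoRecord]) -> list[AnnualClassSummary]:
    """Three-step composition summary for one reservoir.

    Monthly class densities sum species within a class; annual class means
    average over sampled months only (no zero-filling).  Percentages are of
    the year's total mean density; min/max are over the whole input period.
    """
    if not records:
        raise InsufficientDataError("no phytoplankton records")
    reservoirs = {r.reservoir for r in records}
    if len(reservoirs) != 1:
        raise InsufficientDataError(f"records mix reservoirs: {sorted(reservoirs)}")
    reservoir = reservoirs.pop()

    frame = _records_frame(records)
    monthly = (
        frame.groupby(["period", "algal_class"])["density"].sum().unstack(fill_value=0.0)
    )
    period_min = monthly.min()
    period_max = monthly.max()
    species_mean = frame.groupby(["algal_class", "species"])["density"].mean()
    top_species = {
        cls: species_mean[cls].idxmax() for cls in species_mean.index.get_level_values(0).unique()
    }

    out: list[AnnualClassSummary] = []
    for year, chunk in monthly.groupby(monthly.index.year):
        means = chunk.mean()
        total = float(means.sum())
        if total > 0:
            percents = 100.0 * means / total
        else:
            percents = means * 0.0
        out.append(
            AnnualClassSummary(
                reservoir=reservoir,
                year=int(year),
                class_mean={c: float(means[c]) for c in means.index},
                class_percent={c: float(percents[c]) for c in means.index},
                class_min={c: float(period_min[c]) for c in means.index},
                class_max={c: float(period_max[c]) for c in means.index},
                top_species=dict(top_species),
            )
        )
    return out


def bloom_flags(
    records: Sequence[PhytoRecord], bloom_threshold: float = BLOOM_THRESHOLD
) -> pd.DataFrame:
    """Flag reservoir-months whose summed Cyanobacteria density exceeds the
    bloom threshold (strict '>'; default one million cells per liter).

    Returns a frame with columns reservoir, date, cyano_density, bloom.
    """
    if not records:
        return pd.DataFrame(columns=["reservoir", "date", "cyano_density", "bloom"])
    frame = _records_frame(records)
    cyano = (
        frame.assign(
            cyano=np.where(frame["algal_class"] == "Cyanobacteria", frame["density"], 0.0)
        )
        .groupby(["reservoir", "period"])["cyano"]
        .sum()
        .reset_index()
        .rename(columns={"cyano": "cyano_density", "period": "date"})
    )
    cyano["bloom"] = cyano["cyano_density"] > bloom_threshold
    return cyano


def mcyst_total(
    sample: ToxinSample, tol: float = MCYST_CONSISTENCY_TOL
) -> McystTotal:
    """Recompute the total microcystin concentration as in + ex.

    A stored total disagreeing with the recomputed sum by more than ``tol``
    flags the sample as inconsistent (the stored value is preserved, never
    overwritten).  A censored fraction propagates to a censored total.
    """
    if sample.mcyst_in is None or sample.mcyst_ex is None:
        raise InsufficientDataError(
            f"{sample.reservoir} {sample.date} {sample.depth} m: both microcystin "
            "fractions are required to form a total"
        )
    total = sample.mcyst_in + sample.mcyst_ex
    censored = sample.censored_in or sample.censored_ex
    inconsistent: Optional[bool] = None
    if sample.mcyst_tot is not None and not (censored or sample.censored_tot):
        inconsistent = abs(total - sample.mcyst_tot) > tol
        if inconsistent:
            logger.warning(
                "%s %s %.1f m: in+ex=%.2f disagrees with stored total %.2f",
                sample.reservoir, sample.date, sample.depth, total, sample.mcyst_tot,
            )
    return McystTotal(value=float(total), censored=censored, inconsistent=inconsistent)


def who_screen(
    samples: Sequence[ToxinSample], guideline: float = WHO_MCYST_GUIDELINE
) -> ScreeningReport:
    """Screen microcystin samples against the WHO drinking-water guideline.

    Per sample: verdicts for the extracellular fraction and the recomputed
    total versus ``guideline``; report-level maxima use the extracellular
    fraction and the non-censored totals.
    """
    rows = []
    for s in samples:
        try:
            tot = mcyst_total(s)
        except InsufficientDataError:
            tot = None
        rows.append(
            {
                "reservoir": s.reservoir,
                "date": s.date,
                "depth_m": s.depth,
                "density_1e6_cells_L": s.density,
                "mcyst_ex_ug_L": s.mcyst_ex,
                "mcyst_total_ug_L": None if tot is None else tot.value,
                "censored_total": s.censored_tot or (tot.censored if tot else False),
                "ex_exceeds_guideline": (
                    None if s.mcyst_ex is None else bool(s.mcyst_ex > guideline)
                ),
                "total_exceeds_guideline": (
                    None if tot is None else bool(tot.value > guideline)
                ),
                "inconsistent_total": None if tot is None else tot.inconsistent,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "reservoir", "date", "depth_m", "density_1e6_cells_L", "mcyst_ex_ug_L",
            "mcyst_total_ug_L", "censored_total", "ex_exceeds_guideline",
            "total_exceeds_guideline", "inconsistent_total",
        ],
    )
    if table.empty:
        return ScreeningReport(table, None, None, 0, 0, 0, guideline)
    ex = table["mcyst_ex_ug_L"].dropna()
    noncens = table.loc[~table["censored_total"].eq(True), "mcyst_total_ug_L"].dropna()
    return ScreeningReport(
        table=table,
        max_extracellular=None if ex.empty else float(ex.max()),
        max_total_noncensored=None if noncens.empty else float(noncens.max()),
        n_extracellular_exceeding=int((ex > guideline).sum()),
        n_total_exceeding=int(table["total_exceeds_guideline"].eq(True).sum()),
        n_inconsistent=int(table["inconsistent_total"].eq(True).sum()),
        guideline=guideline,
    )


def _parse_censored(raw) -> tuple[Optional[float], bool]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
        return None, False
    text = str(raw).strip()
    if text.startswith(">"):
        return float(text[1:]), True
    return float(text), False


def read_toxin_table(path) -> list[ToxinSample]:
    """Read a microcystin sample CSV (censored cells written as ``>5.0``)."""
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    samples: list[ToxinSample] = []
    for _, row in frame.iterrows():
        mc_in, cen_in = _parse_censored(row.get("mcyst_in_ug_L"))
        mc_ex, cen_ex = _parse_censored(row.get("mcyst_ex_ug_L"))
        mc_tot, cen_tot = _parse_censored(row.get("mcyst_tot_ug_L"))
        samples.append(
            ToxinSample(
                reservoir=str(row["reservoir"]).strip(),
                date=str(row["date"]).strip(),
                depth=float(row["depth_m"]),
                density=float(row["density_1e6_cells_L"]),
                mcyst_in=mc_in,
                mcyst_ex=mc_ex,
                mcyst_tot=mc_tot,
                censored_in=cen_in,
                censored_ex=cen_ex,
                censored_tot=cen_tot,
            )
        )
    return samples


def read_phyto(path) -> list[PhytoRecord]:
    """Read a phytoplankton composition CSV
    (reservoir,date,class,species,density_cells_L)."""
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    return [
        PhytoRecord(
            reservoir=str(row["reservoir"]).strip(),
            date=str(row["date"]).strip(),
            algal_class=str(row["class"]).strip(),
            species=str(row["species"]).strip(),
            density=float(row["density_cells_L"]),
        )
        for _, row in frame.iterrows()
    ]


def write_phyto(records: Iterable[PhytoRecord], path) -> None:
    records = list(records)
    frame = pd.DataFrame(
        {
            "reservoir": [r.reservoir for r in records],
            "date": [r.date for r in records],
            "class": [r.algal_class for r in records],
            "species": [r.species for r in records],
            "density_cells_L": [r.density for r in records],
        }
    )
    frame.to_csv(path, index=False)


def load_microcystin_survey() -> list[ToxinSample]:
    """Bundled 2010-2012 Planktothrix agardhii-rubescens bloom survey of the
    Flumendosa and Mulargia reservoirs (20 water-column samples)."""
    ref = importlib.resources.files("limnoqe.data").joinpath("microcystin_survey.csv")
    with importlib.resources.as_file(ref) as path:
        return read_toxin_table(path)
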