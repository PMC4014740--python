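"""Seeded synthetic monitoring campaign for a four-reservoir system.

Emulates a 1996-2012 monthly limnological survey (204 months, four
reservoirs) so that every pipeline stage -- calibration, TSI computation,
AR forecasting, composition and bloom analytics -- is testable without the
(undeposited) observational database.

Structure of the generator:

* stored volume: seasonal sinusoid plus AR(1) noise, truncated (not
  reflected) to [5%, 100%] of the reservoir's capacity at maximum
  regulation;
* monthly TSI: the lag-1 volume/season recursion itself, so fitted
  forecasting models can be checked against known coefficients;
* chlorophyll-a: the site TSI(Chl) equation inverted on the TSI series;
* spring TP: back-computed from the coming summer's mean Chl through the
  Chl-TP log-log relation (the spring-overturn phosphorus pool is what the
  summer biomass responds to), with optional log10 observation noise;
  non-spring months carry uninformative lognormal backdrop values;
* Secchi depth: the SD-Chl log-log relation plus log10 noise;
* cyanobacteria density: an independent lag-1 recursion in ln space.

Each output field draws from its own child seed stream, so changing one
field's parameters leaves the others' realizations untouched.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError, ValidationError
from .forecast import encode_time
from .io import (
    SPRING_MONTHS,
    SUMMER_MONTHS,
    CalibrationPair,
    MonitoringRecord,
    MonthlySeries,
)
from .trophic import SiteTsiModel

logger = logging.getLogger(__name__)

#: volume at maximum regulation level (10^6 m^3)
RESERVOIR_CAPACITY = {
    "Cixerri": 23.90,
    "Mulargia": 320.70,
    "Flumendosa": 292.90,
    "Is Barrocus": 11.96,
}

#: long-run TSI(Chl) mean targeted per reservoir
RESERVOIR_TSI_MEAN = {
    "Flumendosa": 45.0,
    "Cixerri": 56.0,
    "Is Barrocus": 51.0,
    "Mulargia": 48.0,
}

DEFAULT_CLASS_WEIGHTS = (0.45, 0.25, 0.15, 0.10, 0.05)

_SPECIES = {
    "Cyanobacteria": ("Planktothrix agardhii-rubescens", "Microcystis aeruginosa"),
    "Chlorophyceae": ("Coelastrum reticulatum", "Chlorella sp."),
    "Bacillariophyceae": ("Cyclotella sp.", "Aulacoseira sp."),
    "Cryptophyceae": ("Cryptomonas sp.", "Rhodomonas sp."),
    "Conjugatophyceae": ("Staurastrum sp.", "Cosmarium sp."),
}
_CLASSES = tuple(_SPECIES)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic campaign for one reservoir."""

    reservoir: str
    capacity: float
    months: int = 204
    start: str = "1996-01"
    seed: int = 0
    # stored volume (10^6 m^3)
    vol_mean: float = 0.0
    vol_seasonal_amp: float = 0.0
    vol_ar: float = 0.7
    vol_noise_sd: float = 0.0
    # TSI lag-1 recursion
    tsi_a: float = 0.5
    tsi_b: float = 0.0
    tsi_c: tuple = (1.5, 0.8)
    tsi_d: float = 0.0
    tsi_noise_sd: float = 3.9
    # ln cyanobacteria density lag-1 recursion
    cy_a: float = 0.6
    cy_b: float = 0.0
    cy_c: tuple = (0.8, 0.4)
    cy_d: float = 0.0
    cy_noise_sd: float = 1.3
    # Chl-TP and SD-Chl log10-log10 links
    chl_tp_slope: float = 1.065
    chl_tp_intercept: float = -0.758
    tp_noise_sd: float = 0.03
    sd_chl_slope: float = -0.328
    sd_chl_intercept: float = 0.551
    sd_noise_sd: float = 0.1
    # backdrop (non-spring) TP draws
    tp_log10_mean: float = 0.0
    tp_log10_sd: float = 0.3
    site: SiteTsiModel = field(default_factory=SiteTsiModel)

    def validate(self) -> None:
        if self.months < 24:
            raise ValidationError("months must be >= 24")
        if self.capacity <= 0:
            raise ValidationError("capacity must be > 0")
        for name in ("vol_noise_sd", "tsi_noise_sd", "cy_noise_sd", "tp_noise_sd",
                     "sd_noise_sd", "tp_log10_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("tsi_a", "cy_a"):
            if abs(getattr(self, name)) >= 1:
                raise ValidationError(f"|{name}| must be < 1 (stationarity)")
        if abs(self.vol_ar) >= 1:
            raise ValidationError("|vol_ar| must be < 1")


def default_config(reservoir: str, seed: int = 0, months: int = 204) -> GeneratorConfig:
    """Preset configuration for one of the four system reservoirs.

    Volume bounds come from the reservoir's capacity at maximum regulation;
    the TSI recursion's fixed point is placed at the reservoir's long-run
    TSI(Chl) mean, with innovation noise sized so that simulated monthly TSI
    dispersion and fitted residual errors land at survey-like magnitudes.
    """
    if reservoir not in RESERVOIR_CAPACITY:
        raise UsageError(
            f"unknown reservoir {reservoir!r}; choose from {sorted(RESERVOIR_CAPACITY)}"
        )
    cap = RESERVOIR_CAPACITY[reservoir]
    tsi_mean = RESERVOIR_TSI_MEAN[reservoir]
    site = SiteTsiModel()
    cfg = GeneratorConfig(reservoir=reservoir, capacity=cap, months=months, seed=seed)
    vol_mean = 0.5 * cap
    tsi_b = -2.0 / cap
    tsi_d = tsi_mean * (1.0 - cfg.tsi_a) - tsi_b * vol_mean
    cy_b = -1.0 / cap
    ln_dens_mean = math.log(4e5)
    cy_d = ln_dens_mean * (1.0 - cfg.cy_a) - cy_b * vol_mean
    log10_chl_mean = (tsi_mean - site.chl_intercept) / (site.chl_slope * math.log(10.0))
    tp_log10_mean = (log10_chl_mean - cfg.chl_tp_intercept) / cfg.chl_tp_slope
    return replace(
        cfg,
        vol_mean=vol_mean,
        vol_seasonal_amp=0.2 * cap,
        vol_noise_sd=0.05 * cap,
        tsi_b=tsi_b,
        tsi_d=tsi_d,
        cy_b=cy_b,
        cy_d=cy_d,
        tp_log10_mean=tp_log10_mean,
    )


def _streams(config: GeneratorConfig) -> dict:
    names = ("volume", "tsi", "cyano", "sd", "tp_spring", "tp_backdrop",
             "phyto_total", "phyto_share", "phyto_bloom", "spare")
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def generate_monitoring(config: GeneratorConfig) -> MonthlySeries:
    """Simulate the monthly surface series for one reservoir."""
    config.validate()
    rngs = _streams(config)
    n = config.months
    index = pd.period_range(config.start, periods=n, freq="M")
    months = index.month.to_numpy()
    years = index.year.to_numpy()

    # stored volume: seasonal cycle peaking in spring + AR(1) noise, truncated
    eps_v = rngs["volume"].normal(0.0, config.vol_noise_sd, n)
    u = np.empty(n)
    u[0] = eps_v[0] / math.sqrt(1.0 - config.vol_ar**2) if config.vol_noise_sd > 0 else 0.0
    for t in range(1, n):
        u[t] = config.vol_ar * u[t - 1] + eps_v[t]
    seasonal = config.vol_seasonal_amp * np.sin(2.0 * np.pi * (months - 4) / 12.0)
    v_raw = config.vol_mean + seasonal + u
    lo, hi = 0.05 * config.capacity, config.capacity
    volume = np.clip(v_raw, lo, hi)
    n_trunc = int(np.sum(v_raw != volume))
    if n_trunc:
        logger.info("%s: %d volume value(s) truncated to [%.2f, %.2f]",
                    config.reservoir, n_trunc, lo, hi)

    # monthly TSI: lag-1 volume/season recursion
    T = np.atleast_2d(encode_time(months, "harmonic"))
    c_tsi = np.asarray(config.tsi_c, dtype=float)
    eps_t = rngs["tsi"].normal(0.0, config.tsi_noise_sd, n)
    tsi = np.empty(n)
    prev = (config.tsi_b * config.vol_mean + config.tsi_d) / (1.0 - config.tsi_a)
    for t in range(n):
        prev = (config.tsi_a * prev + config.tsi_b * volume[t]
                + float(c_tsi @ T[t]) + config.tsi_d + eps_t[t])
        tsi[t] = prev

    # chlorophyll: site TSI(Chl) equation inverted
    site = config.site
    chl = np.exp((tsi - site.chl_intercept) / site.chl_slope)
    log10_chl = np.log10(chl)

    # Secchi depth from the SD-Chl relation
    eps_sd = rngs["sd"].normal(0.0, config.sd_noise_sd, n)
    sd = 10.0 ** (config.sd_chl_intercept + config.sd_chl_slope * log10_chl + eps_sd)

    # cyanobacteria density: independent ln-space recursion
    c_cy = np.asarray(config.cy_c, dtype=float)
    eps_c = rngs["cyano"].normal(0.0, config.cy_noise_sd, n)
    ln_d = np.empty(n)
    prev = (config.cy_b * config.vol_mean + config.cy_d) / (1.0 - config.cy_a)
    for t in range(n):
        prev = (config.cy_a * prev + config.cy_b * volume[t]
                + float(c_cy @ T[t]) + config.cy_d + eps_c[t])
        ln_d[t] = prev
    d_cyano = np.exp(ln_d)

    # total phosphorus: springs anticipate the summer biomass through the
    # Chl-TP relation; other months carry backdrop draws
    tp = 10.0 ** rngs["tp_backdrop"].normal(config.tp_log10_mean, config.tp_log10_sd, n)
    spring = np.isin(months, list(SPRING_MONTHS))
    summer = np.isin(months, list(SUMMER_MONTHS))
    for year in np.unique(years):
        in_year = years == year
        chl_summer = chl[in_year & summer]
        idx_spring = np.flatnonzero(in_year & spring)
        if chl_summer.size == 0 or idx_spring.size == 0:
            continue
        log10_tp = (math.log10(chl_summer.mean()) - config.chl_tp_intercept) / config.chl_tp_slope
        noise = rngs["tp_spring"].normal(0.0, config.tp_noise_sd, idx_spring.size)
        tp[idx_spring] = 10.0 ** (log10_tp + noise)

    frame = pd.DataFrame(
        {"chl": chl, "tp": tp, "sd": sd, "d_cyano": d_cyano, "volume": volume},
        index=index,
    )
    return MonthlySeries(config.reservoir, frame)


def generate_records(
    config: GeneratorConfig, depth: float = 0.5
) -> list[MonitoringRecord]:
    """Expand the monthly series to raw surface sampling records."""
    series = generate_monitoring(config)
    records = []
    for period, row in series.frame.iterrows():
        records.append(
            MonitoringRecord(
                reservoir=config.reservoir,
                date=str(period),
                depth=depth,
                chl=float(row["chl"]),
                tp=float(row["tp"]),
                sd=float(row["sd"]),
                d_cyano=float(row["d_cyano"]),
                volume=float(row["volume"]),
            )
        )
    return records


def generate_calibration_pairs(
    n: int,
    rng: np.random.Generator,
    slope: float = 1.065,
    intercept: float = -0.758,
    noise_sd: float = 0.1,
    tp_range: tuple = (5.0, 100.0),
    reservoir: str = "synthetic",
) -> list[CalibrationPair]:
    """Draw spring-TP/summer-Chl pairs from the log10-linear relation.

    TP is log-uniform over ``tp_range`` (ug/L); Chl follows the relation plus
    Gaussian noise of ``noise_sd`` in log10 space.  Used for parameter-recovery
    studies of the calibration fit.
    """
    lo, hi = (math.log10(tp_range[0]), math.log10(tp_range[1]))
    log_tp = rng.uniform(lo, hi, n)
    log_chl = slope * log_tp + intercept + rng.normal(0.0, noise_sd, n)
    return [
        CalibrationPair(reservoir, 2000 + i, float(10.0 ** lt), float(10.0 ** lc))
        for i, (lt, lc) in enumerate(zip(log_tp, log_chl))
    ]


def generate_phyto(
    config: GeneratorConfig,
    class_weights: Sequence[float] = DEFAULT_CLASS_WEIGHTS,
    bloom_rate: float = 0.3,
    concentration: float = 50.0,
    bloom_threshold: float = 1e6,
):
    """Simulate species-level composition records with episodic blooms.

    Monthly class densities perturb ``class_weights`` (Cyanobacteria,
    Chlorophyceae, Bacillariophyceae, Cryptophyceae, Conjugatophyceae) with a
    Dirichlet draw and scale them by a lognormal total held below the bloom
    threshold.  With per-year probability ``bloom_rate`` one month's
    Cyanobacteria density is amplified so it exceeds the threshold and makes
    up at least 90% of the assemblage.
    """
    from .phyto import PhytoRecord  # local import to avoid cycle at module load

    config.validate()
    w = np.asarray(class_weights, dtype=float)
    if w.size != 5 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("class_weights must be 5 non-negative values summing to 1")
    if not 0.0 <= bloom_rate <= 1.0:
        raise ValidationError("bloom_rate must be in [0, 1]")

    rngs = _streams(config)
    rng_total, rng_share, rng_bloom = (
        rngs["phyto_total"], rngs["phyto_share"], rngs["phyto_bloom"],
    )
    index = pd.period_range(config.start, periods=config.months, freq="M")
    years = index.year.to_numpy()

    bloom_month_idx: set[int] = set()
    for year in np.unique(years):
        idx = np.flatnonzero(years == year)
        if rng_bloom.random() < bloom_rate:
            bloom_month_idx.add(int(rng_bloom.choice(idx)))

    nz = np.flatnonzero(w > 0)
    records: list[PhytoRecord] = []
    for i, period in enumerate(index):
        total = 10.0 ** rng_total.normal(5.4, 0.35)
        total = min(total, 0.99 * bloom_threshold)
        shares = np.zeros(5)
        if nz.size == 1:
            shares[nz[0]] = 1.0
        else:
            shares[nz] = rng_share.dirichlet(concentration * w[nz])
        dens = shares * total
        if i in bloom_month_idx:
            others = dens[1:].sum()
            dens[0] = max(2.0 * bloom_threshold, 9.0 * others)
        for cls, cls_density in zip(_CLASSES, dens):
            if cls_density <= 0 and cls != "Cyanobacteria":
                continue
            primary, secondary = _SPECIES[cls]
            records.append(PhytoRecord(config.reservoir, str(period), cls, primary,
                                       0.7 * cls_density))
            records.append(PhytoRecord(config.reservoir, str(period), cls, secondary,
                                       0.3 * cls_density))
    return records
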