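# Methods

## Scope and data model

`limnoqe` operates on monthly limnological monitoring of storage
reservoirs. The atomic observation is one sample (reservoir, year-month,
optional depth, Chl-a in mg/m³, total phosphorus in µg/L, Secchi depth in
m, cyanobacteria density in cells/L, stored volume in 10⁶ m³). Units are
fixed by convention: Chl-a and Secchi depth carry their customary limnology
units, TP in µg/L follows the Carlson trophic-index convention, and volumes
use the 10⁶ m³ scale of reservoir capacity tables.

Raw samples are collapsed to monthly *surface* means: a sample is "surface"
when its depth is ≤ 2.5 m (configurable; samples without a recorded depth
count as surface). Depth-profile structure (stratification) is deliberately
out of scope: the indices below assume a mixed epilimnion, and monthly
surface means are the quantity the forecasting regressions consume. Months
without a usable sample for a field are explicit gaps, and any month
immediately following a gap is excluded from lag-1 fitting rather than
bridged.

## Calibration

Nutrient–biomass–transparency links are fitted as ordinary least squares on
base-10 logs:

* summer mean Chl-a (June–August) against TP at the spring overturn
  (March–April mean), one pair per reservoir-year, all reservoirs pooled;
* Secchi depth against co-observed surface Chl-a, monthly pairs pooled.

Season definitions are configurable; the defaults place the overturn in
March–April and biological summer in June–August, which is appropriate for
a Mediterranean monomictic regime. Pearson r is reported on the
log-transformed pairs and the residual standard error uses an n−2
denominator. Per-reservoir fits are possible by filtering records before
pairing, but the pooled fit is the default because a single regional
relation is what the downstream site equations assume. Robust or nonlinear
alternatives are out of scope: for data of this kind they do not improve
on the log-linear form enough to justify the added machinery.

## Trophic state and the QE index

The transparency-based trophic state index is TSI = 10·(6 − log₂ SD). The
site-specific natural-log forms used throughout are

    TSI(SD)  = 60 − 14.41 ln SD
    TSI(Chl) = 2.05 ln Chl + 52
    TSI(TP)  = 2.19 ln TP + 48.47

`derive_site_model` reconstructs two of these from first principles: the SD
form is the log₂ identity rewritten with slope 10/ln 2 = 14.427 (the 14.41
in the standard form is a rounding-level difference, flagged in the
derivation report, within 0.06 TSI units anywhere in 0.05–20 m); the TP
form is the Chl–TP regression substituted into TSI(Chl), i.e.
tp_slope = 2.05·1.065 = 2.183 and
tp_intercept = 52 + 2.05·(−0.758)·ln 10 = 48.42, within 0.01/0.05 of the
standard coefficients. The TSI(Chl) form itself is taken as given: chaining
the SD–Chl regression through the transparency index instead would give
≈ 4.73 ln Chl + 41.7, which disagrees with the flat 2.05/52 form. The
derivation report states this alternative; the published flat form is used
everywhere because the site equations form one internally consistent set
with it.

QE bins are closed on the left — TSI < 40 → 1, [40, 50) → 2, [50, 70) → 3,
[70, 80) → 4, ≥ 80 → 5 — so a TSI of exactly 40 is mesotrophic (class 2),
consistent with "< 40" defining class 1. TSI values outside [0, 100] are
classified by the same bins and logged, never clamped. The toxic-bloom
override uses a strict inequality: density *exceeding* 100×10⁶ cells/L
(potable-use threshold, configurable) forces QE = 5; a density exactly at
the threshold falls back to the TSI class.

## Forecasting

TSI and ln cyanobacteria density each follow

    x_t = a·x_{t−1} + b·V_t + c·T_t + d + ε_t,

estimated by OLS on all months where x_t, x_{t−1} (consecutive calendar
months) and V_t are available. The seasonal term T_t is a harmonic pair
(sin, cos of 2π·month/12) by default — two coefficients, smooth annual
cycle — or optionally 11 month indicators with January as the reference
level (a 12th dummy would be collinear with the intercept). A reading in
which the season modulates the *slope* on the lagged term (12 interaction
coefficients) was considered and rejected: the additive seasonal term keeps
the model ≤ 13 parameters and is the form that the reported residual-error
magnitudes support. The TSI fed to the model defaults to TSI(Chl), the
biomass-first variant; TP- and SD-based variants are one keyword away.

Densities are floored at 10³ cells/L before the log transform so that
zero-count months remain usable; floored months are counted on the fitted
model. The calibration window is the full available series by default and
is a caller-side choice (slice the series first). Forecast volumes are
exogenous — no inflow/storage mass balance is modeled — and forecasts are
recursive one-step applications; density forecasts are exponentiated back
to cells/L, which also guarantees positivity. With |a| < 1, constant V and
fixed month, the recursion converges geometrically to
(b·V + c·T + d)/(1 − a); this closed form is used as a correctness check in
the tests.

Parameter uncertainty is carried as OLS standard errors with t-based
confidence intervals. With a lagged dependent variable these are
asymptotically valid; at ~200 months the lag coefficient carries a small
negative finite-sample bias, visible as slightly-below-nominal coverage for
`a` in simulation (≈ 0.92 at nominal 0.95).

## Phytoplankton and toxins

Composition processing is the standard three-step survey summary: per-class
mean annual density (absolute and as percent of the year's total),
per-class minimum/maximum over the whole study period, and the most
representative species per class (highest mean density). Annual means
average over sampled months only; unsampled months are not zero-filled,
since sampling frequency varies. A reservoir-month is a bloom when its
summed Cyanobacteria density strictly exceeds 10⁶ cells/L; the criterion is
class-specific (green algae at any density never trigger it) and monotone
in the threshold.

Microcystin samples carry intracellular and extracellular fractions.
Totals are recomputed as in + ex; a stored total deviating from the sum by
more than 0.05 µg/L — half an ulp per addend at the one-decimal precision
these assays are reported at — is flagged inconsistent, and the stored
value is preserved rather than silently corrected. ELISA microtiter assays
are valid over 0–5 ppb, so ">5.0" entries are right-censored: stored at the
bound, flagged, propagated into censored totals, and excluded from means
and maxima unless explicitly requested. Screening compares the
extracellular fraction and the recomputed total against the WHO
drinking-water guideline of 1 µg/L for microcystin-LR. Toxicity is never
predicted from composition; the toxin–producer table is a static annotation
aid.

## Synthetic data generator

The generator emulates a 204-month (17-year), four-reservoir monitoring
campaign. Per reservoir it produces, from one integer seed with an
independent child stream per output field (so changing one field's
parameters leaves the others' draws untouched):

* **volume**: mean at 50% of capacity, a seasonal sinusoid peaking in
  spring (amplitude 20% of capacity) plus AR(1) noise (φ = 0.7, innovation
  5% of capacity), truncated — not reflected — to [5%, 100%] of the
  reservoir's capacity at maximum regulation (Cixerri 23.90, Mulargia
  320.70, Flumendosa 292.90, Is Barrocus 11.96 ×10⁶ m³), truncations
  logged;
* **TSI**: the lag-1 volume/season recursion itself (a = 0.5,
  b = −2/capacity, harmonic c = (1.5, 0.8), innovation SD 3.9), with d
  placed so the fixed point sits at the reservoir's long-run TSI(Chl) mean
  (Flumendosa 45, Mulargia 48, Is Barrocus 51, Cixerri 56). These choices
  make the simulated monthly TSI dispersion (~4.9) and the fitted residual
  error (~3.9) land at survey-like magnitudes, and — because the series is
  generated by the very model the forecaster fits — make coefficient
  recovery a well-posed check;
* **Chl-a**: the TSI(Chl) equation inverted on the TSI series;
* **Secchi depth**: the SD–Chl log-log relation plus log₁₀ noise (SD 0.1);
* **spring TP**: back-computed from the *coming summer's* mean Chl through
  the Chl–TP relation plus log₁₀ observation noise (SD 0.03) — the spring
  overturn phosphorus pool is what the summer biomass responds to, so the
  generator encodes that causal link exactly and the calibration pairing
  recovers the generating slope and intercept (exactly, when observation
  noise is zero). Non-spring months carry uninformative lognormal backdrop
  TP;
* **cyanobacteria density**: an independent lag-1 recursion in ln space
  (a = 0.6, b = −1/capacity, c = (0.8, 0.4), innovation SD 1.3, long-run
  median 4×10⁵ cells/L);
* **composition**: five-class Dirichlet-perturbed shares scaled by a
  lognormal total held below 10⁶ cells/L in ordinary months; with a
  per-year bloom probability, one month's Cyanobacteria density is
  amplified above the bloom threshold and to ≥ 90% of the assemblage.

What the generator does **not** emulate, and what passing tests therefore
do not show about real data: hydrological realism (drought spells,
inflow–storage dynamics); depth structure; measurement error on Chl
(biomass enters the TSI channel noise-free, so the simulated Chl–TP
correlation is near 1 rather than the ~0.8 of field data); TN, grazing and
other density controls beyond volume and season; and realistic absolute
Chl/TP magnitudes — anchoring the TSI(Chl) mean at survey values through
the flat 2.05/52 equation implies Chl around 0.03 mg/m³, orders below field
concentrations, because that equation and survey-scale TSI dispersion are
mutually inconsistent at realistic Chl. The generator is therefore
calibrated in TSI space, the quantity the pipeline classifies and
forecasts, and its nutrient magnitudes should be read as index-consistent
rather than physical. Parameter-recovery studies for the calibration fit
use a separate direct pair generator (TP log-uniform over a configurable
gradient, Chl from the relation plus log₁₀ noise) where measurement noise
is explicit.

## Numerical conventions

* OLS is delegated to statsmodels; tests verify every fit against
  hand-written normal-equation solutions at 1e−10.
* Degenerate designs (constant regressor after log transform, constant
  target, rank-deficient seasonal design) raise a dedicated error instead
  of returning ill-conditioned coefficients.
* A single-value TSI summary reports sd = 0 with a degenerate flag rather
  than NaN.
* Within-month replicate samples are averaged without weighting; record
  order never affects results (aggregation is permutation-invariant).
* Dates are normalized to month resolution (ISO "YYYY-MM"); all internal
  indexing uses monthly period indices.
* Seeds: every stochastic component takes an integer seed; derived streams
  come from seed-sequence spawning, so outputs are bit-reproducible per
  seed.

## Problem sizes

Simulation-based checks use 204-month campaigns and 60-pair calibration
sets, with 200 seeded replicates for recovery/coverage studies and 20 for
the in-suite spot check — sizes at which the asymptotic OLS approximations
are accurate and the full test suite and acceptance script each run in
seconds on one CPU.

## Known limitations

* The forecasting model is a screening-level linear regression: no nutrient
  mass balance, no stratification, no bloom mechanism. Its role is to
  propagate plausible TSI/density trajectories into QE constraints, not to
  predict individual blooms.
* The seasonal volume sinusoid and the harmonic seasonal term overlap, so
  the volume coefficient b is identified mainly by the AR noise in volume;
  its confidence intervals are honest but wide.
* Censored microcystin totals are bounded below, never imputed; maxima over
  censored sets are reported on the non-censored subset only.
* The QE override is binary at the potable threshold; no intermediate
  restriction classes (e.g. irrigation-only) are modeled, though the
  threshold itself is configurable.
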