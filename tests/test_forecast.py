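import math

import numpy as np
import pytest

from limnoqe.errors import DegenerateDesignError, DomainError, UsageError
from limnoqe.forecast import (
    ArModel,
    encode_time,
    fit_ar,
    predict_series,
    qe_scenario,
)
from limnoqe.trophic import SiteTsiModel, tsi_from_chl

from conftest import make_monthly_series, ols_multi_normal_equations


def _simulate_series(a, b, c, d, n=120, noise_sd=0.0, seed=0, start="2000-01"):
    """Build a MonthlySeries whose TSI(Chl) follows the lag-1 recursion."""
    rng = np.random.default_rng(seed)
    months = (np.arange(n) % 12) + 1
    volume = 100.0 + 20.0 * np.cos(2 * np.pi * months / 12) + rng.normal(0, 5.0, n)
    T = np.atleast_2d(encode_time(months, "harmonic"))
    c = np.asarray(c, float)
    x = np.empty(n)
    prev = (b * 100.0 + d) / (1 - a)
    eps = rng.normal(0, noise_sd, n)
    for t in range(n):
        prev = a * prev + b * volume[t] + float(c @ T[t]) + d + eps[t]
        x[t] = prev
    site = SiteTsiModel()
    chl = np.exp((x - site.chl_intercept) / site.chl_slope)
    d_cyano = np.exp(0.3 * x)  # any positive series; not used by tsi target
    return make_monthly_series(start=start, chl=chl, volume=volume, d_cyano=d_cyano), x


class TestEncodeTime:
    def test_harmonic_march_is_unit_sine(self):
        vec = encode_time(3, "harmonic")
        assert vec == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_harmonic_year_sums_to_zero(self):
        total = np.atleast_2d(encode_time(np.arange(1, 13), "harmonic")).sum(axis=0)
        assert total == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_month_indicator_reference_level(self):
        # January is the reference month absorbed by the intercept
        assert encode_time(1, "month") == pytest.approx(np.zeros(11))
        dec = encode_time(12, "month")
        assert dec[-1] == 1.0 and dec[:-1].sum() == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(UsageError):
            encode_time(13, "harmonic")
        with pytest.raises(UsageError):
            encode_time(3, "fourier-of-doom")


class TestFitAr:
    TRUE = dict(a=0.6, b=-0.02, c=(2.0, -1.0), d=20.0)

    def test_noise_free_exact_recovery(self):
        series, _ = _simulate_series(**self.TRUE, noise_sd=0.0)
        model = fit_ar(series, "tsi", "chl")
        assert model.a == pytest.approx(self.TRUE["a"], abs=1e-8)
        assert model.b == pytest.approx(self.TRUE["b"], abs=1e-8)
        assert model.c == pytest.approx(self.TRUE["c"], abs=1e-7)
        assert model.d == pytest.approx(self.TRUE["d"], abs=1e-6)
        assert model.se == pytest.approx(0.0, abs=1e-7)

    def test_matches_normal_equation_oracle(self):
        series, x = _simulate_series(**self.TRUE, noise_sd=2.0, seed=3)
        model = fit_ar(series, "tsi", "chl")
        months = series.frame.index.month.to_numpy()[1:]
        T = np.atleast_2d(encode_time(months, "harmonic"))
        X = np.column_stack([x[:-1], series.frame["volume"].to_numpy()[1:], T,
                             np.ones(len(x) - 1)])
        beta = ols_multi_normal_equations(X, x[1:])
        assert model.params == pytest.approx(beta, abs=1e-8)

    def test_gap_months_excluded(self):
        series, _ = _simulate_series(**self.TRUE, noise_sd=1.0, seed=4)
        series.frame.iloc[60, series.frame.columns.get_loc("chl")] = np.nan
        model = fit_ar(series, "tsi", "chl")
        # both the gap month and its successor lose a usable row
        assert model.n == len(series.frame) - 3

    def test_constant_density_degenerate(self):
        n = 60
        series = make_monthly_series(
            d_cyano=np.full(n, 5e4), volume=np.random.default_rng(0).uniform(80, 120, n)
        )
        with pytest.raises(DegenerateDesignError):
            fit_ar(series, "ln_cyano")

    def test_density_floor_is_counted(self):
        rng = np.random.default_rng(1)
        n = 60
        dens = rng.lognormal(10, 1, n)
        dens[[5, 17]] = 0.0
        series = make_monthly_series(d_cyano=dens, volume=rng.uniform(80, 120, n))
        model = fit_ar(series, "ln_cyano")
        assert model.floored_months == 2

    def test_month_indicator_encoding_fits(self):
        series, _ = _simulate_series(**self.TRUE, noise_sd=1.0, seed=5, n=150)
        model = fit_ar(series, "tsi", "chl", encoding="month")
        assert model.c.shape == (11,)
        assert model.n == 149


class TestPredictSeries:
    def test_persistence_model_is_constant(self):
        model = ArModel("tsi", a=1.0, b=0.0, c=np.zeros(2), d=0.0, r=1.0, se=0.0, n=30)
        out = predict_series(model, 47.0, np.ones(6), [1, 2, 3, 4, 5, 6])
        assert out == pytest.approx(np.full(6, 47.0))

    def test_zero_lag_coefficient_forgets_initial_value(self):
        model = ArModel("tsi", a=0.0, b=0.1, c=np.zeros(2), d=5.0, r=1.0, se=0.0, n=30)
        months = [1, 2, 3]
        a = predict_series(model, 10.0, [50.0, 60.0, 70.0], months)
        b = predict_series(model, 99.0, [50.0, 60.0, 70.0], months)
        assert a == pytest.approx(b)

    def test_three_month_hand_recursion(self):
        model = ArModel("tsi", a=0.5, b=0.01, c=np.array([2.0, 1.0]), d=10.0,
                        r=1.0, se=0.0, n=30)
        out = predict_series(model, 40.0, [100.0, 110.0, 120.0], [3, 4, 5])
        x = 40.0
        expected = []
        for v, m in zip([100.0, 110.0, 120.0], [3, 4, 5]):
            angle = 2 * math.pi * m / 12
            x = 0.5 * x + 0.01 * v + 2.0 * math.sin(angle) + 1.0 * math.cos(angle) + 10.0
            expected.append(x)
        assert out == pytest.approx(expected, abs=1e-12)

    def test_converges_to_closed_form_fixed_point(self):
        model = ArModel("tsi", a=0.7, b=0.02, c=np.array([1.0, -0.5]), d=12.0,
                        r=1.0, se=0.0, n=30)
        v, m = 80.0, 6
        out = predict_series(model, 0.0, np.full(300, v), np.full(300, m))
        T = encode_time(m, "harmonic")
        fixed_point = (model.b * v + float(model.c @ T) + model.d) / (1 - model.a)
        assert out[-1] == pytest.approx(fixed_point, abs=1e-9)
        # geometric approach: error ratio equals a
        err = np.abs(out - fixed_point)
        assert err[10] / err[9] == pytest.approx(0.7, abs=1e-6)

    def test_density_forecasts_are_positive(self):
        model = ArModel("ln_cyano", a=0.5, b=-0.1, c=np.zeros(2), d=-5.0,
                        r=1.0, se=0.0, n=30)
        out = predict_series(model, 1e4, np.full(24, 200.0), (np.arange(24) % 12) + 1)
        assert np.all(out > 0)

    def test_nonfinite_initial_rejected(self):
        model = ArModel("tsi", a=0.5, b=0.0, c=np.zeros(2), d=0.0, r=1.0, se=0.0, n=30)
        with pytest.raises(DomainError):
            predict_series(model, math.nan, [1.0], [1])


class TestQeScenario:
    tsi_model = ArModel("tsi", a=0.0, b=0.0, c=np.zeros(2), d=45.0, r=1.0, se=0.0, n=30)

    def test_bloom_forces_qe_five_everywhere(self):
        cyano = ArModel("ln_cyano", a=0.0, b=0.0, c=np.zeros(2), d=math.log(5e8),
                        r=1.0, se=0.0, n=30)
        scenario = qe_scenario(self.tsi_model, cyano, 45.0, 1e4,
                               np.full(12, 100.0), (np.arange(12) % 12) + 1)
        assert (scenario.frame["qe"] == 5).all()
        assert scenario.frame["tsi"].to_numpy() == pytest.approx(45.0)

    def test_low_density_mesotrophic_scenario(self):
        cyano = ArModel("ln_cyano", a=0.0, b=0.0, c=np.zeros(2), d=0.0,
                        r=1.0, se=0.0, n=30)  # density fixed at exp(0)=1 cell/L
        scenario = qe_scenario(self.tsi_model, cyano, 45.0, 1.0,
                               np.full(12, 100.0), (np.arange(12) % 12) + 1)
        assert (scenario.frame["qe"] == 2).all()

    def test_composition_of_predictors_and_classifier(self, flumendosa_series):
        from limnoqe.trophic import qe_index

        tsi_model = fit_ar(flumendosa_series, "tsi", "chl")
        cy_model = fit_ar(flumendosa_series, "ln_cyano")
        vols = np.full(24, 150.0)
        months = (np.arange(24) % 12) + 1
        scenario = qe_scenario(tsi_model, cy_model, 45.0, 2e5, vols, months,
                               reservoir="Flumendosa", start="2013-01")
        tsi = predict_series(tsi_model, 45.0, vols, months)
        dens = predict_series(cy_model, 2e5, vols, months)
        assert scenario.frame["tsi"].to_numpy() == pytest.approx(tsi)
        assert scenario.frame["d_cyano"].to_numpy() == pytest.approx(dens)
        assert (scenario.frame["qe"].to_numpy() == qe_index(tsi, dens)).all()

    def test_mismatched_models_rejected(self):
        with pytest.raises(UsageError):
            qe_scenario(self.tsi_model, self.tsi_model, 45.0, 1.0, [100.0], [1])
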