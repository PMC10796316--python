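"""Kinetic model fitting: exactness, robustness, ranking and invariances."""

import math

import numpy as np
import pytest

from chromakin.features import ColorTimeSeries
from chromakin.kinetics import (
    FirstOrder,
    FractionalConversion,
    InsufficientDataError,
    ZeroOrder,
    evaluate_kinetic_law,
    fit_first_order,
    fit_fofc,
    fit_zero_order,
    fractional_conversion,
    goodness_of_fit,
    select_model,
)

DAYS = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0)


def _series(values, attribute="L", days=DAYS):
    return ColorTimeSeries(
        attribute=attribute,
        treatment="t",
        days=tuple(days),
        values=tuple(float(v) for v in values),
        sds=(0.0,) * len(days),
    )


def _brute_force_gof(fit, series):
    """Independent residual-sum oracle for R^2 / RMSE."""
    obs, pred = [], []
    for d, v in zip(series.days, series.values):
        if d in fit.excluded_days:
            continue
        obs.append(v)
        pred.append(float(fit.predict(d)))
    obs, pred = np.asarray(obs), np.asarray(pred)
    sse = sum((o - p) ** 2 for o, p in zip(obs, pred))
    sst = sum((o - obs.mean()) ** 2 for o in obs)
    return 1 - sse / sst if sst > 0 else math.nan, math.sqrt(sse / len(obs))


t = np.asarray(DAYS)


class TestExactFits:
    def test_zero_order_exact_linear(self):
        fit = fit_zero_order(_series(100 - 2 * t))
        assert fit.k == pytest.approx(2.0, rel=1e-12)
        assert fit.direction == "decay"
        assert fit.c0 == pytest.approx(100.0)
        assert fit.rsquared == pytest.approx(1.0)
        assert fit.rmse < 1e-8

    def test_first_order_exact_exponential(self):
        fit = fit_first_order(_series(91 * np.exp(-0.03 * t)))
        assert fit.k == pytest.approx(0.03, rel=1e-9)
        assert fit.c0 == pytest.approx(91.0, rel=1e-9)
        assert fit.rsquared == pytest.approx(1.0)
        assert fit.rmse < 1e-8

    def test_first_order_growth_direction(self):
        fit = fit_first_order(_series(5 * np.exp(0.1 * t)))
        assert fit.direction == "growth"
        assert fit.k == pytest.approx(0.1, rel=1e-9)

    def test_fofc_exact_with_known_plateau(self):
        fit = fit_fofc(_series(42 + 49 * np.exp(-0.1 * t)), cinf=42.0)
        assert fit.k == pytest.approx(0.1, rel=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.cinf == 42.0
        assert fit.rsquared == pytest.approx(1.0)
        assert fit.rmse < 1e-8

    def test_fofc_free_plateau_recovers_parameters(self):
        fit = fit_fofc(_series(42 + 49 * np.exp(-0.1 * t)), cinf="fit")
        assert fit.k == pytest.approx(0.1, rel=1e-6)
        assert fit.cinf == pytest.approx(42.0, rel=1e-6)

    def test_constant_series_flagged_degenerate(self):
        for fitter in (fit_zero_order, fit_first_order):
            fit = fitter(_series([80.0] * 6))
            assert fit.k == 0.0
            assert fit.degenerate
            assert math.isnan(fit.rsquared)
            assert fit.rmse == 0.0


class TestInputContracts:
    def test_fewer_than_three_days_rejected(self):
        with pytest.raises(InsufficientDataError, match="3 distinct days"):
            ZeroOrder([0, 3], [90, 80])

    def test_linearized_first_order_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="strictly positive"):
            fit_first_order(_series([5.0, 1.0, -0.5, -1, -2, -3]), method="linearized")

    def test_de_first_order_excludes_day0_and_flags(self):
        values = np.r_[0.0, 10 * np.exp(0.05 * t[1:])]
        fit = fit_first_order(_series(values, attribute="dE"))
        assert fit.excluded_days == (0.0,)
        assert any("dE" in n for n in fit.notes)
        assert fit.k == pytest.approx(0.05, rel=1e-6)

    def test_from_dataframe_constructor(self):
        import pandas as pd

        df = pd.DataFrame({"day": DAYS, "value": 100 - 2 * t}).sample(frac=1, random_state=0)
        fit = ZeroOrder.from_dataframe(df).fit()
        assert fit.k == pytest.approx(2.0)


class TestFractionalConversion:
    def test_first_day_fraction_is_zero(self):
        fc = fractional_conversion(_series(42 + 49 * np.exp(-0.1 * t)), cinf=42.0)
        assert fc.f[0] == 0.0

    def test_endpoint_fraction_of_browning_trajectory(self):
        # C0 = 91, C_t = 67.5, Cinf = 42 -> f = 23.5/49
        series = _series([91.0, 85.0, 80.0, 75.0, 70.0, 67.5])
        fc = fractional_conversion(series, cinf=42.0)
        assert fc.f[-1] == pytest.approx(23.5 / 49, rel=1e-12)
        assert fc.f[-1] == pytest.approx(0.4796, abs=1e-4)

    def test_complete_conversion_day_excluded(self):
        series = _series([91.0, 70.0, 60.0, 50.0, 45.0, 42.0])
        fc = fractional_conversion(series, cinf=42.0)
        assert fc.f[-1] == 1.0
        assert 15.0 in fc.excluded_days

    def test_all_days_at_plateau_raises_insufficient_data(self):
        series = _series([91.0, 42.0, 42.0, 42.0, 42.0, 42.0])
        with pytest.raises(InsufficientDataError, match="excluded"):
            fit_fofc(series, cinf=42.0)

    def test_plateau_equal_to_start_rejected(self):
        series = _series([91.0, 80.0, 70.0, 60.0, 50.0, 45.0])
        with pytest.raises(ValueError, match="C0 equals Cinf"):
            fractional_conversion(series, cinf=91.0)


class TestGoodnessOfFit:
    @pytest.mark.parametrize("generator", ["zero", "first", "fofc"])
    def test_matches_brute_force_residual_oracle(self, generator, rng):
        values = evaluate_kinetic_law(
            generator, t, c0=91.0, k=0.08, direction="decay", cinf=42.0
        ) + rng.normal(0, 1.0, len(t))
        series = _series(values)
        fits = [fit_zero_order(series), fit_first_order(series), fit_fofc(series, cinf="fit")]
        for fit in fits:
            r2, rmse = goodness_of_fit(fit, series)
            oracle_r2, oracle_rmse = _brute_force_gof(fit, series)
            assert r2 == pytest.approx(oracle_r2, abs=1e-12)
            assert rmse == pytest.approx(oracle_rmse, abs=1e-12)
            assert r2 == pytest.approx(fit.rsquared, abs=1e-12)
            assert rmse == pytest.approx(fit.rmse, abs=1e-12)

    def test_mean_predictor_gives_zero_r2(self):
        series = _series([90, 85, 70, 65, 60, 50])
        fit = fit_zero_order(series)
        # forcing slope 0 at the series mean reproduces the R^2=0 definition
        fit.k = 0.0
        fit.c0 = float(np.mean(series.values))
        r2, _ = goodness_of_fit(fit, series)
        assert r2 == pytest.approx(0.0, abs=1e-12)


class TestSelectModel:
    def _fit_all(self, series, cinf="fit"):
        return [fit_zero_order(series), fit_first_order(series), fit_fofc(series, cinf=cinf)]

    def test_higher_r2_wins(self):
        series = _series(91 * np.exp(-0.05 * t))
        ranked = select_model(self._fit_all(series))
        assert ranked[0].rsquared >= ranked[-1].rsquared

    def test_exact_generator_ranks_first(self):
        for generator, kwargs in (
            ("zero", dict(c0=91.0, k=2.0)),
            ("first", dict(c0=91.0, k=0.05)),
            ("fofc", dict(c0=91.0, k=0.12, cinf=42.0)),
        ):
            values = evaluate_kinetic_law(generator, t, direction="decay", **{**kwargs})
            ranked = select_model(self._fit_all(_series(values)))
            assert ranked[0].model == generator, f"{generator} data misidentified"

    def test_tie_broken_by_lower_rmse(self):
        series = _series(91 * np.exp(-0.05 * t))
        a = fit_first_order(series)
        b = fit_zero_order(series)
        b.rsquared = a.rsquared  # force a tie
        b.rmse = a.rmse + 0.1
        assert select_model([b, a])[0] is a

    def test_fewer_than_two_fits_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            select_model([fit_zero_order(_series(100 - 2 * t))])

    def test_degenerate_fit_ranks_last(self):
        good = fit_zero_order(_series(100 - 2 * t))
        flat = fit_zero_order(_series([80.0] * 6))
        assert select_model([flat, good])[0] is good


class TestInvariances:
    def test_k_invariant_to_time_origin_shift(self):
        shifted = t + 7.0
        for fitter, values in (
            (fit_zero_order, 100 - 2 * t),
            (fit_first_order, 91 * np.exp(-0.05 * t)),
        ):
            base = fitter(_series(values))
            moved = fitter(_series(values, days=shifted))
            assert moved.k == pytest.approx(base.k, rel=1e-9)
        base = fit_fofc(_series(42 + 49 * np.exp(-0.1 * t)), cinf=42.0)
        moved = fit_fofc(_series(42 + 49 * np.exp(-0.1 * t), days=shifted), cinf=42.0)
        assert moved.k == pytest.approx(base.k, rel=1e-9)

    def test_noiseless_rmse_below_numerical_floor(self):
        for fitter, values in (
            (fit_zero_order, 100 - 2 * t),
            (fit_first_order, 91 * np.exp(-0.05 * t)),
            (lambda s: fit_fofc(s, cinf=42.0), 42 + 49 * np.exp(-0.1 * t)),
        ):
            assert fitter(_series(values)).rmse < 1e-8


class TestMonteCarloRecovery:
    """Scaled-down parameter-recovery checks (50 simulations each)."""

    @pytest.mark.parametrize(
        "generator,k,tol",
        [("zero", 1.5, 0.05), ("first", 0.05, 0.10), ("fofc", 0.12, 0.15)],
    )
    def test_median_relative_error_within_band(self, generator, k, tol):
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(50):
            curve = evaluate_kinetic_law(
                generator, t, c0=91.0, k=k, direction="decay", cinf=42.0
            )
            vals = (curve[None, :] + rng.normal(0, 0.5, (3, len(t)))).mean(axis=0)
            series = _series(vals)
            if generator == "zero":
                fit = fit_zero_order(series)
            elif generator == "first":
                fit = fit_first_order(series)
            else:
                fit = fit_fofc(series, cinf="fit")
            errs.append(abs(fit.k - k) / k)
        assert np.median(errs) < tol


def test_results_summary_mentions_key_quantities():
    fit = fit_first_order(_series(91 * np.exp(-0.03 * t)))
    text = fit.summary()
    assert "k (per day)" in text and "0.03" in text
    assert "R^2" in text and "RMSE" in text
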