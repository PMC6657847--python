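"""Harmonic model fitting, calibration protocol, and the transfer function."""

import numpy as np
import pandas as pd
import pytest

import overwinter as ow
from overwinter.harmonic import W


def _dates(n, start="2000-01-01"):
    return pd.date_range(start, periods=n, freq="D")


def _noiseless(n=1461, b0=15.0, b1=1e-4, c1=10.0, s1=2.0, start="2000-01-01",
               variable="water"):
    dates = _dates(n, start)
    t = np.arange(n, dtype=float)
    vals = b0 + b1 * t + c1 * np.cos(W * t) + s1 * np.sin(W * t)
    return ow.DailySeries(dates, vals, variable=variable), (b0, b1, c1, s1)


class TestFitHarmonic:
    def test_constant_series(self):
        s = ow.DailySeries(_dates(1461), np.full(1461, 10.0), variable="water")
        fit = ow.fit_harmonic(s, time_origin="2000-01-01")
        assert fit.b0 == pytest.approx(10.0, abs=1e-9)
        assert fit.b1 == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fit.cos_coef, 0.0, atol=1e-9)
        np.testing.assert_allclose(fit.sin_coef, 0.0, atol=1e-9)

    def test_noiseless_coefficients_recovered(self):
        s, (b0, b1, c1, s1) = _noiseless()
        fit = ow.fit_harmonic(s, time_origin="2000-01-01")
        assert fit.b0 == pytest.approx(b0, abs=1e-6)
        assert fit.b1 == pytest.approx(b1, abs=1e-6)
        assert fit.cos_coef[0] == pytest.approx(c1, abs=1e-6)
        assert fit.sin_coef[0] == pytest.approx(s1, abs=1e-6)
        assert fit.rmse == pytest.approx(0.0, abs=1e-6)

    def test_noisy_fit_within_inflated_standard_errors(self):
        phi, sd = 0.8, 1.5
        s, (b0, b1, c1, s1) = _noiseless(n=10_000)
        rng = np.random.default_rng(8)
        noise = np.empty(len(s))
        noise[0] = rng.normal(0, sd)
        e = sd * np.sqrt(1 - phi ** 2)
        for i in range(1, len(s)):
            noise[i] = phi * noise[i - 1] + rng.normal(0, e)
        noisy = ow.DailySeries(s.dates, s.values + noise, variable="water")
        fit = ow.fit_harmonic(noisy, time_origin="2000-01-01")
        # OLS standard errors assume white residuals; AR(1) noise inflates
        # the true sampling error by the square root of the noise spectral
        # density ratio at the relevant frequency, ~= sqrt((1+phi)/(1-phi))
        # at low frequency.  4 inflated SEs is the analytic contract.
        inflate = np.sqrt((1 + phi) / (1 - phi))
        assert abs(fit.b0 - b0) < 4 * inflate * fit.sds["b0"]
        assert abs(fit.b1 - b1) < 4 * inflate * fit.sds["b1"]
        assert abs(fit.cos_coef[0] - c1) < 4 * inflate * fit.sds["cos"][0]
        assert abs(fit.sin_coef[0] - s1) < 4 * inflate * fit.sds["sin"][0]

    def test_short_series_rejected(self):
        s, _ = _noiseless(n=600)
        with pytest.raises(ValueError, match="annual cycles"):
            ow.fit_harmonic(s)

    def test_round_trip_serialization(self):
        s, _ = _noiseless()
        fit = ow.fit_harmonic(s, time_origin="2000-01-01")
        back = ow.HarmonicFit.from_dict(fit.to_dict())
        t = np.linspace(0, 2000, 50)
        np.testing.assert_allclose(back.evaluate(t), fit.evaluate(t))


class TestCalibrationSplit:
    def _series(self, n=3000):
        s, _ = _noiseless(n=n)
        return s

    def test_partition_arithmetic(self):
        s = self._series()
        cal, val = ow.calibration_split(s, 0.3, seed=0)
        n_cal = cal.observed_mask.sum()
        n_val = val.observed_mask.sum()
        assert n_cal == round(0.3 * 3000)
        assert n_cal + n_val == 3000
        assert not (cal.observed_mask & val.observed_mask).any()

    def test_deterministic_under_seed(self):
        s = self._series()
        a1, _ = ow.calibration_split(s, 0.3, seed=5)
        a2, _ = ow.calibration_split(s, 0.3, seed=5)
        np.testing.assert_array_equal(a1.observed_mask, a2.observed_mask)

    def test_inclusion_frequency_is_binomial(self):
        s = self._series(n=1000)
        day = 137
        hits = 0
        n_rep = 2000
        for seed in range(n_rep):
            cal, _ = ow.calibration_split(s, 0.3, seed=seed)
            hits += bool(cal.observed_mask[day])
        phat = hits / n_rep
        se = np.sqrt(0.3 * 0.7 / n_rep)
        assert abs(phat - 0.3) < 4 * se

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ow.calibration_split(self._series(), 1.5, seed=0)


class TestBuildTransfer:
    def test_identity(self):
        s, _ = _noiseless()
        fit = ow.fit_harmonic(s, time_origin="2000-01-01")
        tf = ow.build_transfer(fit, fit)
        np.testing.assert_allclose(tf.cr, 1.0)
        np.testing.assert_allclose(tf.sr, 1.0)
        assert tf.trend_ratio == pytest.approx(1.0)

    def test_forced_division(self):
        a, _ = _noiseless(c1=10.0, s1=2.0)
        w, _ = _noiseless(c1=9.0, s1=1.8)
        af = ow.fit_harmonic(a, time_origin="2000-01-01")
        wf = ow.fit_harmonic(w, time_origin="2000-01-01")
        tf = ow.build_transfer(af, wf)
        assert tf.cr[0] == pytest.approx(0.9, abs=1e-9)
        assert tf.sr[0] == pytest.approx(0.9, abs=1e-9)

    def test_random_coefficients_match_elementwise_division(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            ca, sa = rng.uniform(1, 20, 2)
            cw, sw = rng.uniform(1, 20, 2)
            a, _ = _noiseless(c1=ca, s1=sa)
            w, _ = _noiseless(c1=cw, s1=sw)
            tf = ow.build_transfer(ow.fit_harmonic(a, time_origin="2000-01-01"),
                                   ow.fit_harmonic(w, time_origin="2000-01-01"))
            assert tf.cr[0] == pytest.approx(cw / ca, rel=1e-6)
            assert tf.sr[0] == pytest.approx(sw / sa, rel=1e-6)

    def test_zero_air_coefficient_rejected(self):
        a, _ = _noiseless(c1=0.0)
        w, _ = _noiseless()
        with pytest.raises(ValueError, match="zero"):
            ow.build_transfer(ow.fit_harmonic(a, time_origin="2000-01-01"),
                              ow.fit_harmonic(w, time_origin="2000-01-01"))

    def test_mismatched_stage_rejected(self):
        a, _ = _noiseless()
        af = ow.fit_harmonic(a, time_origin="2000-01-01", stage="calibration")
        wf = ow.fit_harmonic(a, time_origin="2000-01-01", stage="final")
        with pytest.raises(ValueError, match="stage"):
            ow.build_transfer(af, wf)


class TestPredictWater:
    def test_identity_reproduces_water_fit(self):
        s, _ = _noiseless()
        fit = ow.fit_harmonic(s, time_origin="2000-01-01")
        tf = ow.build_transfer(fit, fit)
        pred = ow.predict_water(tf, tf.water_base, s.dates)
        np.testing.assert_allclose(pred.values,
                                   fit.evaluate(fit.time_index(s.dates)),
                                   atol=1e-9)

    def test_known_ratios_recover_true_water(self):
        a, (b0, b1, ca, sa) = _noiseless(c1=10.0, s1=2.0)
        t = np.arange(len(a), dtype=float)
        wvals = b0 + b1 * t + 0.9 * ca * np.cos(W * t) + 0.9 * sa * np.sin(W * t)
        w = ow.DailySeries(a.dates, wvals, variable="water")
        tf = ow.build_transfer(ow.fit_harmonic(a, time_origin="2000-01-01"),
                               ow.fit_harmonic(w, time_origin="2000-01-01"))
        pred = ow.predict_water(tf, tf.air_shape, a.dates)
        np.testing.assert_allclose(pred.values, wvals, atol=1e-6)

    def test_periodic_up_to_trend(self):
        s, _ = _noiseless()
        fit = ow.fit_harmonic(s, time_origin="2000-01-01")
        t = np.linspace(0, 1000, 37)
        for k in (1, 3):
            diff = fit.evaluate(t + 365.25 * k) - fit.evaluate(t)
            np.testing.assert_allclose(diff, fit.b1 * 365.25 * k, atol=1e-9)

    def test_dates_before_origin_rejected(self):
        s, _ = _noiseless()
        fit = ow.fit_harmonic(s, time_origin="2000-01-01")
        tf = ow.build_transfer(fit, fit)
        with pytest.raises(ValueError, match="origin"):
            ow.predict_water(tf, fit, pd.date_range("1990-01-01", periods=5))


class TestValidateFit:
    def test_perfect_prediction_gives_zero(self):
        s, _ = _noiseless()
        fit = ow.fit_harmonic(s, time_origin="2000-01-01")
        assert ow.validate_fit(fit, s) == pytest.approx(0.0, abs=1e-9)

    def test_unit_residuals(self):
        s, _ = _noiseless(n=1461)
        fit = ow.fit_harmonic(s, time_origin="2000-01-01")
        shifted = ow.DailySeries(s.dates[:2],
                                 fit.evaluate(fit.time_index(s.dates[:2]))
                                 + np.array([1.0, -1.0]),
                                 variable="water")
        assert ow.validate_fit(fit, shifted) == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_residual_rmse(self):
        s, _ = _noiseless(n=5000)
        fit = ow.fit_harmonic(s, time_origin="2000-01-01")
        rng = np.random.default_rng(9)
        noisy = ow.DailySeries(s.dates, s.values + rng.normal(0, 2.0, len(s)),
                               variable="water")
        assert ow.validate_fit(fit, noisy) == pytest.approx(2.0, abs=0.05)

    def test_empty_holdout_rejected(self):
        s, _ = _noiseless()
        fit = ow.fit_harmonic(s, time_origin="2000-01-01")
        empty = ow.DailySeries(s.dates, np.full(len(s), np.nan), variable="water")
        with pytest.raises(ValueError, match="empty"):
            ow.validate_fit(fit, empty)


def test_final_rmse_not_worse_than_validation_stage_on_noiseless_data():
    # an exactly specified model can only improve with more data
    s, _ = _noiseless(n=2922)
    cal, val = ow.calibration_split(s, 0.3, seed=2)
    fit_cal = ow.fit_harmonic(cal, time_origin="2000-01-01", stage="calibration")
    fit_final = ow.fit_harmonic(s, time_origin="2000-01-01", stage="final")
    assert ow.validate_fit(fit_final, val) <= ow.validate_fit(fit_cal, val) + 1e-12


def test_transfer_ratio_recovery_within_propagated_errors(sim_config):
    """Median absolute ratio error over repeated synthetic fits is small
    relative to the propagated standard errors."""
    import dataclasses
    errors, ses = [], []
    for seed in range(30):
        cfg = dataclasses.replace(sim_config, seed=seed,
                                  start="2000-01-01", end="2005-12-31")
        air, water, truth = ow.generate_pair(cfg, with_gaps=False)
        af = ow.fit_harmonic(air, time_origin=cfg.origin)
        wf = ow.fit_harmonic(water, time_origin=cfg.origin)
        tf = ow.build_transfer(af, wf)
        errors.append(abs(tf.cr[0] - cfg.cr[0]))
        ses.append(tf.cr_sd[0])
    assert np.median(errors) < 2 * np.median(ses)
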