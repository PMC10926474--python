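import datetime as dt

import numpy as np
import pytest

import beetlecast as bc
from beetlecast.degree_days import daily_degree_days, resolve_biofix


def quadrature_half_day(t_low, t_high, th, n=100_001):
    """Independent oracle: numerically integrate the thresholded sine trace
    max(0, min(T(θ), T_U) − T_L) over θ ∈ [−π/2, π/2], normalised by 2π."""
    theta = np.linspace(-np.pi / 2, np.pi / 2, n)
    m = 0.5 * (t_low + t_high)
    alpha = 0.5 * (t_high - t_low)
    trace = m + alpha * np.sin(theta)
    integrand = np.maximum(0.0, np.minimum(trace, th.upper) - th.lower)
    return np.trapezoid(integrand, theta) / (2 * np.pi)


class TestSimpleDaily:
    @pytest.mark.parametrize(
        "tmin,tmax,expected",
        [
            (15, 15, 0.0),        # average sits exactly on the lower threshold
            (10, 30, 5.0),        # T_avg 20, between thresholds
            (25, 35, 6.7),        # T_avg 30 >= T_U: horizontal cutoff caps at span
            (0, 10, 0.0),         # cold day floors at zero
        ],
    )
    def test_examples(self, tmin, tmax, expected, thresholds):
        assert bc.simple_daily_dd(tmin, tmax, thresholds) == pytest.approx(expected)

    def test_inverted_extremes_rejected(self, thresholds):
        with pytest.raises(ValueError):
            bc.simple_daily_dd(20, 10, thresholds)

    def test_extremes_are_not_preclamped(self, thresholds):
        # method 1: a freezing tmin drags the average down even when tmax is warm
        assert bc.simple_daily_dd(-10, 35, thresholds) == 0.0


class TestSineHalfDay:
    def test_entirely_below_lower_threshold(self, thresholds):
        assert bc.sine_half_day_dd(5, 14, thresholds) == 0.0

    def test_entirely_above_upper_threshold(self, thresholds):
        assert bc.sine_half_day_dd(25, 30, thresholds) == pytest.approx(3.35)

    def test_spanning_both_thresholds(self, thresholds):
        # frozen from the quadrature oracle for (10, 30) between 15 / 21.7 °C
        assert bc.sine_half_day_dd(10, 30, thresholds) == pytest.approx(
            1.8553857119, abs=1e-8
        )

    def test_flat_half_day_degenerate(self, thresholds):
        assert bc.sine_half_day_dd(18, 18, thresholds) == pytest.approx(1.5)
        assert bc.sine_half_day_dd(30, 30, thresholds) == pytest.approx(3.35)
        assert bc.sine_half_day_dd(10, 10, thresholds) == 0.0

    def test_closed_form_matches_quadrature_over_all_branches(self, rng):
        """1,000 randomized (t_low, t_high, T_L, T_U) cases plus constructed
        corner cases; closed form agrees with the integral to 1e-6 °C-days."""
        cases = []
        for _ in range(1000):
            t_low = rng.uniform(-10, 38)
            t_high = t_low + rng.uniform(0, 28)
            lower = rng.uniform(0, 15)
            upper = lower + rng.uniform(4, 22)
            cases.append((t_low, t_high, lower, upper))
        # one constructed case per branch of the six-case closed form
        cases += [
            (5, 12, 15, 25),    # all below T_L
            (26, 33, 15, 25),   # all above T_U
            (16, 24, 15, 25),   # entirely between
            (10, 20, 15, 25),   # crosses T_L only
            (16, 30, 15, 25),   # crosses T_U only
            (10, 30, 15, 25),   # crosses both
        ]
        branches = set()
        for t_low, t_high, lower, upper in cases:
            th = bc.ThermalThresholds(lower, upper)
            closed = bc.sine_half_day_dd(t_low, t_high, th)
            oracle = quadrature_half_day(t_low, t_high, th)
            assert abs(closed - oracle) <= 1e-6, (t_low, t_high, lower, upper)
            branches.add(
                (t_high <= lower, t_low >= upper, t_low < lower, t_high > upper)
            )
        assert len(branches) >= 6


class TestSineDaily:
    def test_constant_temperature_accumulates_linearly(self, thresholds):
        rec = bc.DailyWeatherRecord(dt.date(2020, 7, 1), 18, 18)
        assert bc.sine_daily_dd(rec, 18, thresholds) == pytest.approx(3.0)

    def test_symmetric_next_day_doubles_the_half_day(self, thresholds):
        rec = bc.DailyWeatherRecord(dt.date(2020, 7, 1), 12, 28)
        expected = 2 * bc.sine_half_day_dd(12, 28, thresholds)
        assert bc.sine_daily_dd(rec, 12, thresholds) == pytest.approx(expected)

    def test_asymmetric_day_matches_per_half_quadrature(self, thresholds):
        rec = bc.DailyWeatherRecord(dt.date(2020, 7, 1), 10, 30)
        got = bc.sine_daily_dd(rec, 16, thresholds)
        oracle = quadrature_half_day(10, 30, thresholds) + quadrature_half_day(
            16, 30, thresholds
        )
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_simple_and_sine_agree_when_within_thresholds(self, rng):
        # with T_L <= tmin <= tmax <= T_U the sine area reduces to the mean
        th = bc.ThermalThresholds(10.0, 30.0)
        for _ in range(50):
            tmin = rng.uniform(10, 28)
            tmax = rng.uniform(tmin, 30)
            rec = bc.DailyWeatherRecord(dt.date(2020, 7, 1), tmin, tmax)
            assert bc.sine_daily_dd(rec, tmin, th) == pytest.approx(
                bc.simple_daily_dd(tmin, tmax, th), abs=1e-12
            )


class TestAccumulate:
    def _series(self, tmins, tmaxs, year=2020, start=(1, 1)):
        d0 = dt.date(year, *start)
        recs = [
            bc.DailyWeatherRecord(d0 + dt.timedelta(days=k), lo, hi)
            for k, (lo, hi) in enumerate(zip(tmins, tmaxs))
        ]
        return bc.WeatherSeries("S", year, recs)

    def test_saturated_days_hit_the_cap(self, thresholds):
        series = self._series([30] * 10, [40] * 10)
        params = bc.DegreeDayParams("simple", thresholds)
        acc = bc.accumulate(series, params)
        assert acc.cumulative_dd[-1] == pytest.approx(10 * thresholds.span)

    @pytest.mark.parametrize("method", ["simple", "sine"])
    def test_monotone_and_capped(self, method, thresholds, rng):
        tmins = rng.uniform(-5, 25, size=60)
        tmaxs = tmins + rng.uniform(0, 15, size=60)
        series = self._series(list(tmins), list(tmaxs))
        acc = bc.accumulate(series, bc.DegreeDayParams(method, thresholds))
        assert np.all(np.diff(acc.cumulative_dd) >= 0)
        assert np.all(acc.daily_dd >= 0)
        assert np.all(acc.daily_dd <= thresholds.span + 1e-12)

    @pytest.mark.parametrize("method", ["simple", "sine"])
    def test_matches_day_by_day_recomputation(self, method, thresholds, rng):
        tmins = rng.uniform(0, 25, size=30)
        tmaxs = tmins + rng.uniform(0, 15, size=30)
        series = self._series(list(tmins), list(tmaxs))
        acc = bc.accumulate(series, bc.DegreeDayParams(method, thresholds))
        # oracle: independent loop over single-day calls
        expected = []
        for k, rec in enumerate(series.records):
            if method == "simple":
                expected.append(bc.simple_daily_dd(rec.tmin, rec.tmax, thresholds))
            else:
                nxt = series.records[k + 1].tmin if k + 1 < len(series) else None
                expected.append(bc.sine_daily_dd(rec, nxt, thresholds))
        np.testing.assert_allclose(acc.daily_dd, expected, atol=1e-12)
        np.testing.assert_allclose(acc.cumulative_dd, np.cumsum(expected), atol=1e-9)

    def test_widening_thresholds_never_decreases_daily_dd(self, rng):
        tmins = rng.uniform(-5, 25, size=40)
        tmaxs = tmins + rng.uniform(0, 15, size=40)
        series = self._series(list(tmins), list(tmaxs))
        narrow = bc.ThermalThresholds(12.0, 24.0)
        wide = bc.ThermalThresholds(10.0, 28.0)
        for method in ("simple", "sine"):
            d_narrow = daily_degree_days(series, method, narrow)
            d_wide = daily_degree_days(series, method, wide)
            assert np.all(d_wide >= d_narrow - 1e-12)

    def test_series_starting_after_biofix_rejected(self, thresholds):
        series = self._series([10] * 5, [20] * 5, start=(6, 1))
        with pytest.raises(ValueError, match="biofix"):
            bc.accumulate(series, bc.DegreeDayParams("simple", thresholds))

    def test_biofix_resolves_per_year(self):
        assert resolve_biofix((3, 1), 2020).timetuple().tm_yday == 61  # leap
        assert resolve_biofix((3, 1), 2021).timetuple().tm_yday == 60
        assert resolve_biofix(50, 2020) == dt.date(2020, 2, 19)  # literal mode


class TestDateAtDd:
    def _constant_acc(self, rate=5.0, n=40, year=2021):
        d0 = dt.date(year, 1, 1)
        recs = [
            bc.DailyWeatherRecord(d0 + dt.timedelta(days=k), 15 + rate, 15 + rate)
            for k in range(n)
        ]
        series = bc.WeatherSeries("S", year, recs)
        params = bc.DegreeDayParams("simple", bc.ThermalThresholds(15, 100))
        return bc.accumulate(series, params)

    def test_zero_target_returns_first_accumulation_date(self):
        acc = self._constant_acc()
        assert bc.date_at_dd(acc, 0.0) == 1.0

    def test_constant_rate_arithmetic(self):
        acc = self._constant_acc(rate=5.0)
        assert bc.date_at_dd(acc, 50.0) == pytest.approx(10.0)
        assert bc.date_at_dd(acc, 47.5) == pytest.approx(9.5)

    def test_unreached_target_signals_none(self):
        acc = self._constant_acc(rate=5.0, n=10)
        assert bc.date_at_dd(acc, 1e6) is None

    def test_ceiling_mode_returns_first_crossing_day(self):
        acc = self._constant_acc(rate=5.0)
        assert bc.date_at_dd(acc, 47.5, interpolate=False) == 10.0

    def test_matches_linear_scan_oracle(self, thresholds, rng):
        tmins = rng.uniform(5, 25, size=120)
        tmaxs = tmins + rng.uniform(0, 15, size=120)
        d0 = dt.date(2021, 1, 1)
        recs = [
            bc.DailyWeatherRecord(d0 + dt.timedelta(days=k), lo, hi)
            for k, (lo, hi) in enumerate(zip(tmins, tmaxs))
        ]
        series = bc.WeatherSeries("S", 2021, recs)
        acc = bc.accumulate(series, bc.DegreeDayParams("simple", thresholds))
        total = acc.cumulative_dd[-1]
        for target in rng.uniform(1e-6, total, size=100):
            got = bc.date_at_dd(acc, target)
            # oracle: explicit linear scan with within-day interpolation
            prev = 0.0
            for k, cum in enumerate(acc.cumulative_dd):
                if cum >= target:
                    frac = (target - prev) / acc.daily_dd[k]
                    expected = acc.julian[k] - 1 + frac
                    break
                prev = cum
            assert got == pytest.approx(expected, abs=1e-9)
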