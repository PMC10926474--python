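"""Degree-day accumulation with lower/upper thresholds and a biofix date.

Two daily calculations are provided:

* **simple** (average method 1): daily DD is the mean of tmin and tmax,
  capped at the upper threshold T_U (horizontal cutoff), minus the lower
  threshold T_L, floored at zero.  The extremes are *not* clamped before
  averaging.
* **sine** (half-day sine wave): the within-day temperature trace is modelled
  per half day as ``T(θ) = m + α·sin θ`` over ``θ ∈ [-π/2, π/2]`` between a
  low and a high extreme; daily DD is the thresholded area under that curve.
  By default the second half day runs from the day's maximum down to the
  *following* day's minimum (double-sine convention); a switch uses the same
  day's extremes for both half days.

Accumulated degree-days ``D`` start at zero on the day before the biofix and
are the independent variable of the emergence model.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .weather import DailyWeatherRecord, WeatherSeries

__all__ = [
    "ThermalThresholds",
    "DegreeDayParams",
    "AccumulationSeries",
    "simple_daily_dd",
    "sine_half_day_dd",
    "sine_daily_dd",
    "daily_degree_days",
    "accumulate",
    "date_at_dd",
    "resolve_biofix",
]


@dataclass(frozen=True)
class ThermalThresholds:
    """Lower and upper developmental thresholds in °C (lower < upper)."""

    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(
                f"lower threshold ({self.lower}) must be < upper ({self.upper})"
            )

    @property
    def span(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class DegreeDayParams:
    """One degree-day model: calculation method, thresholds and biofix.

    ``biofix`` is either a ``(month, day)`` tuple resolved per calendar year
    (so "Mar 1" is day-of-year 60 or 61 depending on leap year), or an
    integer day-of-year applied literally in every year.
    """

    method: str
    thresholds: ThermalThresholds
    biofix: tuple[int, int] | int = (1, 1)

    def __post_init__(self):
        if self.method not in ("simple", "sine"):
            raise ValueError(f"unknown method {self.method!r}")


def resolve_biofix(biofix: tuple[int, int] | int, year: int) -> dt.date:
    """Resolve a biofix spec to a calendar date in the given year."""
    if isinstance(biofix, int):
        return dt.date(year, 1, 1) + dt.timedelta(days=biofix - 1)
    month, day = biofix
    return dt.date(year, month, day)


# ---------------------------------------------------------------------------
# daily calculations


def simple_daily_dd(tmin: float, tmax: float, th: ThermalThresholds) -> float:
    """Average-method daily degree-days with horizontal upper cutoff.

    ``max(0, min(T_avg, T_U) - T_L)`` with ``T_avg = (tmin + tmax) / 2``.
    The extremes are averaged as observed (no pre-clamping).
    """
    if tmin > tmax:
        raise ValueError(f"tmin ({tmin}) > tmax ({tmax})")
    t_avg = 0.5 * (tmin + tmax)
    return float(max(0.0, min(t_avg, th.upper) - th.lower))


def _sine_half_day(t_low, t_high, lower: float, upper: float):
    """Vectorized half-day sine-wave accumulation, °C-days.

    Thresholded area of ``m + α·sin θ`` over ``θ ∈ [-π/2, π/2]`` divided by
    2π (a half day is half of the 2π-normalised daily cycle).
    """
    t_low = np.asarray(t_low, dtype=float)
    t_high = np.asarray(t_high, dtype=float)
    m = 0.5 * (t_low + t_high)
    alpha = 0.5 * (t_high - t_low)
    span = upper - lower

    with np.errstate(divide="ignore", invalid="ignore"):
        s1 = np.clip((lower - m) / np.where(alpha > 0, alpha, np.nan), -1.0, 1.0)
        s2 = np.clip((upper - m) / np.where(alpha > 0, alpha, np.nan), -1.0, 1.0)
        th1 = np.arcsin(s1)
        th2 = np.arcsin(s2)

    half_pi = 0.5 * np.pi
    inv2pi = 1.0 / (2.0 * np.pi)

    # six cases, resolved most-specific first
    out = np.where(
        t_high <= lower,
        0.0,
        np.where(
            t_low >= upper,
            0.5 * span,
            np.where(
                (t_low >= lower) & (t_high <= upper),
                0.5 * (m - lower),
                np.where(
                    (t_low < lower) & (t_high <= upper),
                    inv2pi * ((m - lower) * (half_pi - th1) + alpha * np.cos(th1)),
                    np.where(
                        t_low >= lower,  # and t_high > upper
                        inv2pi
                        * (
                            (m - lower) * (th2 + half_pi)
                            - alpha * np.cos(th2)
                            + span * (half_pi - th2)
                        ),
                        inv2pi
                        * (
                            (m - lower) * (th2 - th1)
                            + alpha * (np.cos(th1) - np.cos(th2))
                            + span * (half_pi - th2)
                        ),
                    ),
                ),
            ),
        ),
    )
    # degenerate flat half-day (alpha == 0): constant temperature m
    flat = alpha == 0
    if np.any(flat):
        const = 0.5 * np.maximum(0.0, np.minimum(m, upper) - lower)
        out = np.where(flat, const, out)
    return out


def sine_half_day_dd(t_low: float, t_high: float, th: ThermalThresholds) -> float:
    """Half-day sine-wave degree-days between one low and one high extreme."""
    if t_low > t_high:
        raise ValueError(f"t_low ({t_low}) > t_high ({t_high})")
    return float(_sine_half_day(t_low, t_high, th.lower, th.upper))


def sine_daily_dd(
    day: DailyWeatherRecord,
    next_day_tmin: float | None,
    th: ThermalThresholds,
) -> float:
    """Full-day sine-wave degree-days: rising half day from (tmin, tmax) plus
    falling half day from tmax down to the next day's tmin.

    For the final day of a series (``next_day_tmin`` absent) the falling half
    day reuses the same day's tmin.  If the following minimum exceeds the
    day's maximum the falling half day is flat at tmax.
    """
    nxt = day.tmin if next_day_tmin is None else next_day_tmin
    half1 = sine_half_day_dd(day.tmin, day.tmax, th)
    half2 = sine_half_day_dd(min(nxt, day.tmax), day.tmax, th)
    return half1 + half2


def daily_degree_days(
    series: WeatherSeries,
    method: str,
    th: ThermalThresholds,
    double_sine: bool = True,
) -> np.ndarray:
    """Daily degree-days for every day of the series (vectorized)."""
    tmin = series.tmin
    tmax = series.tmax
    if method == "simple":
        t_avg = 0.5 * (tmin + tmax)
        return np.maximum(0.0, np.minimum(t_avg, th.upper) - th.lower)
    if method == "sine":
        half1 = _sine_half_day(tmin, tmax, th.lower, th.upper)
        if double_sine:
            nxt = np.append(tmin[1:], tmin[-1])
        else:
            nxt = tmin
        half2 = _sine_half_day(np.minimum(nxt, tmax), tmax, th.lower, th.upper)
        return half1 + half2
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# accumulation


@dataclass
class AccumulationSeries:
    """Daily and cumulative degree-days from the biofix onward.

    ``cumulative_dd[k]`` is the total accumulated by the *end* of
    ``dates[k]``; accumulation is zero on the day before the biofix.
    """

    dates: list[dt.date]
    daily_dd: np.ndarray
    cumulative_dd: np.ndarray

    @property
    def julian(self) -> np.ndarray:
        return np.array([d.timetuple().tm_yday for d in self.dates], dtype=float)

    @property
    def total(self) -> float:
        return float(self.cumulative_dd[-1])

    def dd_on(self, date: dt.date) -> float:
        """Cumulative degree-days at the end of ``date`` (0 before biofix)."""
        if date < self.dates[0]:
            return 0.0
        idx = (date - self.dates[0]).days
        if idx >= len(self.dates):
            raise ValueError(f"{date} is past the end of the accumulation series")
        return float(self.cumulative_dd[idx])


def accumulate(
    series: WeatherSeries,
    params: DegreeDayParams,
    double_sine: bool = True,
) -> AccumulationSeries:
    """Accumulate degree-days from the biofix to the end of the series."""
    biofix = resolve_biofix(params.biofix, series.year)
    if series.start_date > biofix:
        raise ValueError(
            f"series for {series.site_id} {series.year} starts {series.start_date}, "
            f"after the biofix {biofix}"
        )
    daily_all = daily_degree_days(series, params.method, params.thresholds, double_sine)
    offset = (biofix - series.start_date).days
    daily = daily_all[offset:]
    dates = series.dates[offset:]
    return AccumulationSeries(
        dates=dates, daily_dd=daily, cumulative_dd=np.cumsum(daily)
    )


def date_at_dd(
    acc: AccumulationSeries,
    target: float,
    interpolate: bool = True,
) -> float | None:
    """Fractional day-of-year at which accumulation first reaches ``target``.

    Returns ``None`` when the target exceeds the season total ("not
    reached").  With ``interpolate=True`` (default) the crossing is placed
    linearly within the crossing day; otherwise the first whole day whose
    cumulative total meets the target is returned.
    """
    if target < 0:
        raise ValueError("target must be >= 0")
    julian = acc.julian
    if target == 0:
        return float(julian[0])
    cum = acc.cumulative_dd
    idx = int(np.searchsorted(cum, target))
    if idx >= len(cum):
        return None
    if not interpolate:
        return float(julian[idx])
    prev = cum[idx - 1] if idx > 0 else 0.0
    daily = acc.daily_dd[idx]
    frac = (target - prev) / daily if daily > 0 else 1.0
    return float(julian[idx] - 1.0 + frac)
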