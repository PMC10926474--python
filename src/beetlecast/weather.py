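"""Daily min/max temperature series: reading, validation, conversion, aggregation.

The downstream degree-day calculations only ever consume daily temperature
extremes, so this module reduces everything (including sub-daily logger
readings) to one ``(tmin, tmax)`` pair per calendar day.  The canonical
internal unit is degrees Celsius; Fahrenheit appears only at I/O boundaries.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeatherRecord",
    "WeatherSeries",
    "WeatherValidationError",
    "fahrenheit_to_celsius",
    "celsius_to_fahrenheit",
    "read_weather_csv",
    "write_weather_csv",
    "aggregate_subdaily_to_daily",
]


class WeatherValidationError(ValueError):
    """Raised when a temperature series violates its invariants."""


def fahrenheit_to_celsius(f):
    """Convert °F to °C via C = (F - 32) * 5/9."""
    return (np.asarray(f, dtype=float) - 32.0) * 5.0 / 9.0


def celsius_to_fahrenheit(c):
    """Convert °C to °F via F = C * 9/5 + 32."""
    return np.asarray(c, dtype=float) * 9.0 / 5.0 + 32.0


@dataclass(frozen=True)
class DailyWeatherRecord:
    """One day's temperature extremes in °C."""

    date: dt.date
    tmin: float
    tmax: float

    def __post_init__(self):
        if self.tmin > self.tmax:
            raise WeatherValidationError(
                f"tmin ({self.tmin}) > tmax ({self.tmax}) on {self.date}"
            )


@dataclass
class WeatherSeries:
    """A gap-free, date-ordered run of daily temperature extremes for one site-year.

    Invariants: dates strictly increasing with no missing days between the
    first and last record; ``tmin <= tmax`` everywhere (enforced per record).
    """

    site_id: str
    year: int
    records: list[DailyWeatherRecord] = field(default_factory=list)

    def __post_init__(self):
        if not self.records:
            raise WeatherValidationError("no records")
        prev = None
        for rec in self.records:
            if prev is not None:
                delta = (rec.date - prev).days
                if delta <= 0:
                    raise WeatherValidationError(
                        f"dates not strictly increasing at {rec.date}"
                    )
                if delta > 1:
                    raise WeatherValidationError(
                        f"gap of {delta - 1} day(s) before {rec.date}; "
                        "fill or reject gaps explicitly"
                    )
            prev = rec.date

    def __len__(self) -> int:
        return len(self.records)

    @property
    def start_date(self) -> dt.date:
        return self.records[0].date

    @property
    def end_date(self) -> dt.date:
        return self.records[-1].date

    @property
    def dates(self) -> list[dt.date]:
        return [r.date for r in self.records]

    @property
    def tmin(self) -> np.ndarray:
        return np.array([r.tmin for r in self.records], dtype=float)

    @property
    def tmax(self) -> np.ndarray:
        return np.array([r.tmax for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": pd.to_datetime(self.dates),
                "tmin": self.tmin,
                "tmax": self.tmax,
            }
        )


def _fill_gaps(frame: pd.DataFrame, max_gap: int) -> pd.DataFrame:
    """Linearly interpolate runs of <= max_gap missing days (tmin and tmax
    separately); longer runs still raise downstream."""
    frame = frame.set_index("date").asfreq("D")
    missing = frame["tmin"].isna()
    if missing.any():
        # identify run lengths of consecutive missing days
        runs = (missing != missing.shift()).cumsum()
        lengths = missing.groupby(runs).transform("sum")
        ok = ~missing | (lengths <= max_gap)
        if ok.all():
            frame = frame.interpolate(method="time")
    return frame.reset_index()


def read_weather_csv(
    path,
    unit: str = "celsius",
    site_id: str | None = None,
    year: int | None = None,
    fill_gaps: bool = False,
    max_gap: int = 3,
) -> WeatherSeries:
    """Read a ``date,tmin,tmax`` CSV into a validated :class:`WeatherSeries`.

    Parameters
    ----------
    unit:
        ``"celsius"``/``"C"`` or ``"fahrenheit"``/``"F"``; Fahrenheit inputs
        are converted on read so the returned series is always in °C.
    fill_gaps:
        If True, gaps of at most ``max_gap`` consecutive missing days are
        filled by linear interpolation of tmin and tmax separately.  By
        default any gap is rejected, since degree-day accumulation requires
        a complete series.
    """
    frame = pd.read_csv(path)
    required = {"date", "tmin", "tmax"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise WeatherValidationError(
            f"missing column(s) {sorted(missing_cols)} in {path}"
        )
    if frame.empty:
        raise WeatherValidationError(f"no records in {path}")
    try:
        frame["date"] = pd.to_datetime(frame["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise WeatherValidationError(f"unparseable date in {path}: {exc}") from exc
    frame = frame.sort_values("date").reset_index(drop=True)
    if fill_gaps:
        frame = _fill_gaps(frame, max_gap)

    unit_key = unit.strip().lower()[0]
    if unit_key == "f":
        frame["tmin"] = fahrenheit_to_celsius(frame["tmin"])
        frame["tmax"] = fahrenheit_to_celsius(frame["tmax"])
    elif unit_key != "c":
        raise ValueError(f"unknown unit {unit!r}; expected celsius or fahrenheit")

    bad = frame["tmin"] > frame["tmax"]
    if bad.any():
        first = frame.loc[bad, "date"].iloc[0].date()
        raise WeatherValidationError(f"tmin > tmax on {first}")

    records = [
        DailyWeatherRecord(d.date(), float(lo), float(hi))
        for d, lo, hi in zip(frame["date"], frame["tmin"], frame["tmax"])
    ]
    first_date = records[0].date
    return WeatherSeries(
        site_id=site_id if site_id is not None else "unknown",
        year=year if year is not None else first_date.year,
        records=records,
    )


def write_weather_csv(series: WeatherSeries, path) -> None:
    """Write a WeatherSeries as ``date,tmin,tmax`` (ISO dates, °C)."""
    frame = series.to_frame()
    frame["date"] = frame["date"].dt.strftime("%Y-%m-%d")
    frame.to_csv(path, index=False)


def aggregate_subdaily_to_daily(
    readings: Iterable[tuple[dt.datetime, float]],
    site_id: str = "unknown",
    year: int | None = None,
) -> WeatherSeries:
    """Collapse sub-daily logger readings (e.g. 2-hourly) to daily extremes.

    Each calendar day's ``tmin``/``tmax`` are the minimum and maximum of that
    day's readings.  A day with zero readings strictly inside the covered
    span is a gap and raises :class:`WeatherValidationError`.
    """
    readings = list(readings)
    if not readings:
        raise WeatherValidationError("no readings")
    frame = pd.DataFrame(readings, columns=["timestamp", "temp"])
    frame["day"] = pd.to_datetime(frame["timestamp"]).dt.date
    grouped = frame.groupby("day")["temp"].agg(["min", "max"]).sort_index()
    records = [
        DailyWeatherRecord(day, float(row["min"]), float(row["max"]))
        for day, row in grouped.iterrows()
    ]
    return WeatherSeries(
        site_id=site_id,
        year=year if year is not None else records[0].date.year,
        records=records,
    )
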