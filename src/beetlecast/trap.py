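"""Trap-catch reduction: raw per-trap observations to cumulative-proportion curves.

Traps at a site are pooled (summed) within each collection date; the season's
cumulative catch divided by the season total gives the cumulative trap-catch
proportion, the dependent variable of the emergence model.  Quantities may be
beetle counts or volumetric measurements (ml) interchangeably — only
proportions propagate downstream.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrapObservation",
    "SiteYearCurve",
    "TrapValidationError",
    "read_trap_csv",
    "write_trap_csv",
    "build_curve",
    "observed_date_at_proportion",
]


class TrapValidationError(ValueError):
    """Raised when trap observations violate their invariants."""


@dataclass(frozen=True)
class TrapObservation:
    """One trap's catch quantity on one collection date."""

    site_id: str
    date: dt.date
    trap_id: str
    quantity: float

    def __post_init__(self):
        if self.quantity < 0:
            raise TrapValidationError(
                f"negative quantity {self.quantity} for {self.site_id}/"
                f"{self.trap_id} on {self.date}"
            )


@dataclass
class SiteYearCurve:
    """Cumulative trap-catch proportion curve for one site-year.

    ``cumulative_proportion`` is non-decreasing, ends at exactly 1, and is
    aligned with strictly increasing ``obs_dates``.
    """

    site_id: str
    year: int
    obs_dates: list[dt.date]
    interval_quantity: np.ndarray
    cumulative_proportion: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.cumulative_proportion) < 0):
            raise TrapValidationError("cumulative proportion must be non-decreasing")
        if not np.isclose(self.cumulative_proportion[-1], 1.0):
            raise TrapValidationError("cumulative proportion must end at 1")

    @property
    def julian(self) -> np.ndarray:
        return np.array([d.timetuple().tm_yday for d in self.obs_dates], dtype=float)

    @property
    def season_total(self) -> float:
        return float(self.interval_quantity.sum())


def read_trap_csv(path) -> list[TrapObservation]:
    """Read a ``site,date,trap,quantity`` CSV into validated observations."""
    frame = pd.read_csv(path)
    required = {"site", "date", "trap", "quantity"}
    missing = required - set(frame.columns)
    if missing:
        raise TrapValidationError(f"missing column(s) {sorted(missing)} in {path}")
    try:
        frame["date"] = pd.to_datetime(frame["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise TrapValidationError(f"unparseable date in {path}: {exc}") from exc
    neg = frame["quantity"] < 0
    if neg.any():
        row = frame.loc[neg].iloc[0]
        raise TrapValidationError(
            f"negative quantity on row ({row['site']}, {row['date'].date()}, "
            f"{row['trap']})"
        )
    dupes = frame.duplicated(subset=["site", "date", "trap"])
    if dupes.any():
        row = frame.loc[dupes].iloc[0]
        raise TrapValidationError(
            f"duplicate (site, date, trap) key ({row['site']}, "
            f"{row['date'].date()}, {row['trap']})"
        )
    return [
        TrapObservation(str(r["site"]), r["date"].date(), str(r["trap"]),
                        float(r["quantity"]))
        for _, r in frame.iterrows()
    ]


def write_trap_csv(observations: Sequence[TrapObservation], path) -> None:
    frame = pd.DataFrame(
        {
            "site": [o.site_id for o in observations],
            "date": [o.date.isoformat() for o in observations],
            "trap": [o.trap_id for o in observations],
            "quantity": [o.quantity for o in observations],
        }
    )
    frame.to_csv(path, index=False)


def build_curve(
    observations: Iterable[TrapObservation],
    year: int | None = None,
) -> SiteYearCurve:
    """Pool traps by date and reduce one site-year to a cumulative curve.

    Raises if the observations span several sites, have fewer than two
    distinct dates, or total zero seasonal catch.
    """
    obs = list(observations)
    if not obs:
        raise TrapValidationError("no observations")
    sites = {o.site_id for o in obs}
    if len(sites) != 1:
        raise TrapValidationError(f"observations span multiple sites: {sorted(sites)}")
    per_date: dict[dt.date, float] = {}
    for o in obs:
        per_date[o.date] = per_date.get(o.date, 0.0) + o.quantity
    dates = sorted(per_date)
    if len(dates) < 2:
        raise TrapValidationError("need at least two observation dates")
    interval = np.array([per_date[d] for d in dates], dtype=float)
    total = interval.sum()
    if total <= 0:
        raise TrapValidationError("no catch: zero season total")
    return SiteYearCurve(
        site_id=sites.pop(),
        year=year if year is not None else dates[0].year,
        obs_dates=dates,
        interval_quantity=interval,
        cumulative_proportion=np.cumsum(interval) / total,
    )


def observed_date_at_proportion(
    curve: SiteYearCurve,
    p: float,
    acc=None,
) -> float:
    """Observed fractional day-of-year at which cumulative catch reaches ``p``.

    Interpolates linearly on the calendar-day axis between the bracketing
    observations.  With ``acc`` (an :class:`~beetlecast.degree_days.AccumulationSeries`)
    supplied, interpolation is done on the accumulated degree-day axis
    instead and the crossing converted back to a date.

    If the very first observation already meets ``p`` the first observation
    date is returned with a left-censoring warning.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    cum = curve.cumulative_proportion
    idx = int(np.searchsorted(cum, p))
    if idx == 0:
        warnings.warn(
            f"{curve.site_id} {curve.year}: first observation already at "
            f"cumulative proportion {cum[0]:.3f} >= {p}; observed date is "
            "left-censored",
            stacklevel=2,
        )
        return float(curve.julian[0])
    c0, c1 = cum[idx - 1], cum[idx]
    if c1 == p:
        return float(curve.julian[idx])
    if acc is None:
        x = curve.julian
        x0, x1 = x[idx - 1], x[idx]
        return float(x0 + (p - c0) / (c1 - c0) * (x1 - x0))
    from .degree_days import date_at_dd  # local import avoids cycle

    d0 = acc.dd_on(curve.obs_dates[idx - 1])
    d1 = acc.dd_on(curve.obs_dates[idx])
    target = d0 + (p - c0) / (c1 - c0) * (d1 - d0)
    result = date_at_dd(acc, target)
    if result is None:  # pragma: no cover - target lies within the season
        raise ValueError("interpolated degree-day target not reached")
    return result
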