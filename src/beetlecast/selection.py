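"""Exhaustive grid search over degree-day model parameters.

Every combination of calculation method, start (biofix) date, and lower and
upper thresholds is evaluated on the development site-years: degree-days are
accumulated per site-year, the pooled (D, cumulative proportion) points are
fitted with the log-logistic emergence curve, and the candidate is scored by
Lin's concordance correlation coefficient (CCC) between predicted and
observed dates of 10% trap-catch, with AIC as the tie-break.  The default
grid spans lower thresholds 32–59 °F and upper thresholds 68–100 °F in 1 °F
steps, four start dates and two methods — 28 × 33 × 4 × 2 = 7,392
candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .degree_days import (
    AccumulationSeries,
    DegreeDayParams,
    ThermalThresholds,
    accumulate,
    daily_degree_days,
    date_at_dd,
    resolve_biofix,
)
from .emergence import FitError, FitResult, dd_at_proportion, fit_log_logistic
from .trap import SiteYearCurve, observed_date_at_proportion
from .weather import WeatherSeries, fahrenheit_to_celsius

__all__ = [
    "GridSpec",
    "AgreementStats",
    "CandidateResult",
    "SelectionReport",
    "concordance",
    "enumerate_grid",
    "evaluate_candidate",
    "rank_and_select",
    "grid_search",
]

#: default start dates: Jan 1, Feb 1, Mar 1, Apr 1 (resolved per year)
DEFAULT_START_DATES: tuple[tuple[int, int], ...] = ((1, 1), (2, 1), (3, 1), (4, 1))

#: literal day-of-year alternative for the start dates
LITERAL_JULIAN_START_DATES: tuple[int, ...] = (1, 32, 50, 91)


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid in °F (inclusive bounds, integer °F steps).

    The thresholds are specified in °F because a 1 °F lattice over
    lower 32–59 and upper 68–100 is what yields the canonical 7,392-candidate
    grid; values are converted to °C for all computation.
    """

    lower_f: tuple[float, float, float] = (32.0, 59.0, 1.0)
    upper_f: tuple[float, float, float] = (68.0, 100.0, 1.0)
    start_dates: tuple = DEFAULT_START_DATES
    methods: tuple[str, ...] = ("simple", "sine")

    def _axis(self, bounds) -> np.ndarray:
        lo, hi, step = bounds
        if step <= 0:
            raise ValueError("step must be > 0")
        vals = np.arange(lo, hi + 0.5 * step, step)
        if len(vals) == 0:
            raise ValueError("empty threshold range")
        return vals

    @property
    def lower_values_f(self) -> np.ndarray:
        return self._axis(self.lower_f)

    @property
    def upper_values_f(self) -> np.ndarray:
        return self._axis(self.upper_f)

    @property
    def size(self) -> int:
        return (
            len(self.lower_values_f)
            * len(self.upper_values_f)
            * len(self.start_dates)
            * len(self.methods)
        )


@dataclass(frozen=True)
class AgreementStats:
    """Lin's concordance decomposition: CCC = precision (r) × accuracy (A)."""

    ccc: float
    precision: float
    accuracy: float


@dataclass
class CandidateResult:
    """One grid cell: fitted curve, DD at 10%, per-site-year dates, agreement."""

    params: DegreeDayParams
    fit: FitResult | None
    dd10: float | None
    predicted_dates: dict
    observed_dates: dict
    agreement: AgreementStats | None
    excluded_site_years: tuple = ()

    @property
    def scorable(self) -> bool:
        return self.agreement is not None


@dataclass
class SelectionReport:
    ranked: list[CandidateResult]
    selected: CandidateResult
    aic_rank_of_selected: int


def concordance(x: Sequence[float], y: Sequence[float]) -> AgreementStats:
    """Lin's concordance correlation coefficient with its decomposition.

    CCC = 2·cov(x, y) / (var(x) + var(y) + (mean(x) − mean(y))²) using
    population (1/n) moments; precision r is the Pearson correlation and
    accuracy A = CCC / r is the bias-correction factor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n) moments
    if vx == 0 or vy == 0:
        raise ValueError("zero variance: concordance undefined")
    sxy = np.mean((x - mx) * (y - my))
    ccc = 2.0 * sxy / (vx + vy + (mx - my) ** 2)
    r = sxy / np.sqrt(vx * vy)
    if r == 0:
        raise ValueError("zero correlation: accuracy factor undefined")
    return AgreementStats(ccc=float(ccc), precision=float(r), accuracy=float(ccc / r))


def enumerate_grid(spec: GridSpec | None = None) -> list[DegreeDayParams]:
    """All candidate parameter sets in deterministic
    (method, start date, lower, upper) order, thresholds converted to °C."""
    spec = spec or GridSpec()
    lowers_c = fahrenheit_to_celsius(spec.lower_values_f)
    uppers_c = fahrenheit_to_celsius(spec.upper_values_f)
    out: list[DegreeDayParams] = []
    for method in spec.methods:
        for start in spec.start_dates:
            for lo in lowers_c:
                for hi in uppers_c:
                    if lo >= hi:
                        continue
                    out.append(
                        DegreeDayParams(
                            method=method,
                            thresholds=ThermalThresholds(float(lo), float(hi)),
                            biofix=start,
                        )
                    )
    if not out:
        raise ValueError("grid is empty")
    return out


def _accumulation_for(
    series: WeatherSeries,
    params: DegreeDayParams,
    dd_cache: dict | None,
) -> AccumulationSeries:
    """Accumulate from the biofix, optionally reusing cached daily DD arrays
    (the daily values depend only on method + thresholds, not the biofix)."""
    if dd_cache is None:
        return accumulate(series, params)
    key = (
        params.method,
        params.thresholds.lower,
        params.thresholds.upper,
        series.site_id,
        series.year,
    )
    daily_all = dd_cache.get(key)
    if daily_all is None:
        daily_all = daily_degree_days(series, params.method, params.thresholds)
        dd_cache[key] = daily_all
    biofix = resolve_biofix(params.biofix, series.year)
    if series.start_date > biofix:
        raise ValueError(
            f"series for {series.site_id} {series.year} starts after biofix {biofix}"
        )
    offset = (biofix - series.start_date).days
    daily = daily_all[offset:]
    return AccumulationSeries(
        dates=series.dates[offset:],
        daily_dd=daily,
        cumulative_dd=np.cumsum(daily),
    )


def evaluate_candidate(
    dev_data: Sequence[tuple[WeatherSeries, SiteYearCurve]],
    params: DegreeDayParams,
    p: float = 0.10,
    dd_cache: dict | None = None,
) -> CandidateResult:
    """Score one parameter combination on the development site-years.

    Pools (D, cumulative proportion) points across site-years (dropping
    observation dates with zero accumulated degree-days, whose log transform
    is undefined), fits the emergence curve, inverts it at ``p`` and compares
    predicted against observed dates of ``p`` trap-catch with Lin's CCC.
    Site-years whose season never reaches the fitted degree-day target are
    excluded with a warning; a candidate with fewer than two comparable
    site-years, or an unfittable point cloud, is returned unscorable.
    """
    points: list[tuple[float, float]] = []
    accs: list[tuple[str, int, AccumulationSeries, SiteYearCurve]] = []
    for series, curve in dev_data:
        acc = _accumulation_for(series, params, dd_cache)
        accs.append((curve.site_id, curve.year, acc, curve))
        for date, prop in zip(curve.obs_dates, curve.cumulative_proportion):
            D = acc.dd_on(date)
            if D > 0:
                points.append((D, float(prop)))
    # deterministic point order: results must not depend on site-year order
    points.sort()

    def _unscorable(excluded=()):
        return CandidateResult(
            params=params, fit=None, dd10=None, predicted_dates={},
            observed_dates={}, agreement=None, excluded_site_years=tuple(excluded),
        )

    try:
        fit = fit_log_logistic(points)
    except (ValueError, FitError):  # unfittable candidate, rank last
        return _unscorable()
    if fit.curve.slope <= 0:
        return _unscorable()
    dd_target = dd_at_proportion(fit.curve, p)

    predicted: dict = {}
    observed: dict = {}
    excluded = []
    for site, year, acc, curve in accs:
        pred = date_at_dd(acc, dd_target)
        if pred is None:
            warnings.warn(
                f"{site} {year}: degree-day target {dd_target:.1f} not reached "
                "this season; site-year excluded from agreement",
                stacklevel=2,
            )
            excluded.append((site, year))
            continue
        predicted[(site, year)] = pred
        observed[(site, year)] = observed_date_at_proportion(curve, p)

    if len(predicted) < 2:
        result = _unscorable(excluded)
        result.fit = fit
        result.dd10 = float(dd_target)
        return result

    keys = sorted(predicted)
    agreement = concordance(
        [predicted[k] for k in keys], [observed[k] for k in keys]
    )
    return CandidateResult(
        params=params,
        fit=fit,
        dd10=float(dd_target),
        predicted_dates=predicted,
        observed_dates=observed,
        agreement=agreement,
        excluded_site_years=tuple(excluded),
    )


def rank_and_select(candidates: Sequence[CandidateResult]) -> SelectionReport:
    """Stable-sort candidates by (CCC descending, AIC ascending); the first is
    selected.  Unscorable candidates rank below every scorable one.  Also
    reports the selected candidate's ordinal rank by AIC alone."""
    scorable = [c for c in candidates if c.scorable]
    if not scorable:
        raise ValueError("no scorable candidates")

    def sort_key(item):
        idx, c = item
        if not c.scorable:
            return (1, 0.0, 0.0, idx)
        return (0, -c.agreement.ccc, c.fit.aic, idx)

    ranked = [c for _, c in sorted(enumerate(candidates), key=sort_key)]
    selected = ranked[0]
    by_aic = sorted(scorable, key=lambda c: c.fit.aic)
    aic_rank = 1 + by_aic.index(selected)
    return SelectionReport(ranked=ranked, selected=selected,
                           aic_rank_of_selected=aic_rank)


def grid_search(
    dev_data: Sequence[tuple[WeatherSeries, SiteYearCurve]],
    spec: GridSpec | None = None,
    p: float = 0.10,
    progress: bool = False,
) -> SelectionReport:
    """Evaluate the full grid on the development data and select the optimum.

    Daily degree-day arrays are cached per (method, thresholds, site-year),
    so the four start dates sharing a threshold pair reuse one computation;
    results are identical to evaluating each candidate independently.
    """
    candidates = enumerate_grid(spec)
    dd_cache: dict = {}
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, params in enumerate(candidates):
            results.append(evaluate_candidate(dev_data, params, p=p, dd_cache=dd_cache))
            if progress and (i + 1) % 500 == 0:
                print(f"  evaluated {i + 1}/{len(candidates)} candidates")
    return rank_and_select(results)
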