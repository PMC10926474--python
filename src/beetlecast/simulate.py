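"""Synthetic weather and trap-catch generation for desk-scale studies.

The generator emulates the statistical structure the pipeline assumes:

* temperate-zone daily min/max temperatures as a seasonal sinusoid with
  AR(1)-correlated daily-mean noise (so synthetic heat waves produce the
  multi-day accumulation bursts seen in real degree-day series);
* twice-weekly (or weekly) trap-catch counts whose expected cumulative
  proportion follows the log-logistic emergence curve in degree-days
  accumulated under a known "true" model;
* multi-site-year studies with site-to-site phenology variation (jittered
  mean climate and seasonal peak), split into development and validation
  halves.

Defaults describe a Minnesota-like climate in which adult activity runs from
mid-June into September.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .degree_days import DegreeDayParams, ThermalThresholds, accumulate, date_at_dd
from .emergence import EmergenceCurve, dd_at_proportion, predict_proportion
from .trap import TrapObservation, build_curve, write_trap_csv
from .weather import DailyWeatherRecord, WeatherSeries, write_weather_csv

__all__ = [
    "WeatherGenConfig",
    "TrapGenConfig",
    "StudySiteYear",
    "generate_weather",
    "generate_trap_catch",
    "generate_study",
    "DEFAULT_TRUE_PARAMS",
    "DEFAULT_TRUE_CURVE",
]

#: the published optimum model: simple method, 15/21.7 °C, Jan 1 biofix
DEFAULT_TRUE_PARAMS = DegreeDayParams(
    method="simple", thresholds=ThermalThresholds(15.0, 21.7), biofix=(1, 1)
)

#: published emergence-curve coefficients (intercept −43.34, slope 7.41)
DEFAULT_TRUE_CURVE = EmergenceCurve(slope=7.41, intercept=-43.34)


@dataclass(frozen=True)
class WeatherGenConfig:
    """Seasonal-sinusoid weather generator with AR(1) daily-mean noise.

    Daily mean temperature is
    ``annual_mean + seasonal_amplitude · sin(2π(d − peak_day + 91.25)/365.25)``
    plus AR(1) noise (lag-1 ``noise_autocorrelation``, Normal innovations of
    sd ``noise_sd``); tmin/tmax sit ``diurnal_range/2`` below/above it.
    """

    annual_mean: float = 7.0
    seasonal_amplitude: float = 16.0
    peak_day: int = 200
    diurnal_range: float = 10.0
    noise_sd: float = 3.0
    noise_autocorrelation: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.seasonal_amplitude < 0 or self.noise_sd < 0 or self.diurnal_range < 0:
            raise ValueError("amplitudes and standard deviations must be >= 0")
        if not 0 <= self.noise_autocorrelation < 1:
            raise ValueError("noise_autocorrelation must be in [0, 1)")


@dataclass(frozen=True)
class TrapGenConfig:
    """Trap-catch sampler driven by a known emergence model.

    ``obs_interval`` of 3.5 days approximates twice-weekly collection; 7 is
    weekly.  ``count_noise`` draws interval counts either multinomially with
    total ``season_total`` or as independent Poissons with the same means.
    """

    true_params: DegreeDayParams = DEFAULT_TRUE_PARAMS
    true_curve: EmergenceCurve = DEFAULT_TRUE_CURVE
    first_obs_day: int = 166
    last_obs_day: int = 272
    obs_interval: float = 3.5
    season_total: float = 10_000.0
    count_noise: str = "multinomial"
    n_traps: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.obs_interval <= 0:
            raise ValueError("obs_interval must be > 0")
        if self.season_total <= 0:
            raise ValueError("season_total must be > 0")
        if self.count_noise not in ("multinomial", "poisson"):
            raise ValueError("count_noise must be 'multinomial' or 'poisson'")


def generate_weather(
    config: WeatherGenConfig, year: int, site_id: str = "SYN"
) -> WeatherSeries:
    """Generate one full calendar year of daily min/max temperatures."""
    rng = np.random.default_rng(config.seed)
    start = dt.date(year, 1, 1)
    n_days = (dt.date(year + 1, 1, 1) - start).days
    d = np.arange(1, n_days + 1, dtype=float)
    mean = config.annual_mean + config.seasonal_amplitude * np.sin(
        2.0 * np.pi * (d - config.peak_day + 91.25) / 365.25
    )
    rho = config.noise_autocorrelation
    noise = np.zeros(n_days)
    if config.noise_sd > 0:
        stationary_sd = config.noise_sd / np.sqrt(1.0 - rho**2) if rho else config.noise_sd
        noise[0] = rng.normal(0.0, stationary_sd)
        innov = rng.normal(0.0, config.noise_sd, size=n_days - 1)
        for t in range(1, n_days):
            noise[t] = rho * noise[t - 1] + innov[t - 1]
    mean = mean + noise
    half = 0.5 * config.diurnal_range
    records = [
        DailyWeatherRecord(start + dt.timedelta(days=int(k)), float(m - half),
                           float(m + half))
        for k, m in enumerate(mean)
    ]
    return WeatherSeries(site_id=site_id, year=year, records=records)


def _observation_days(config: TrapGenConfig) -> list[int]:
    days, k = [], 0
    while True:
        day = config.first_obs_day + int(round(k * config.obs_interval))
        if day > config.last_obs_day:
            break
        if not days or day > days[-1]:
            days.append(day)
        k += 1
    return days


def generate_trap_catch(
    weather: WeatherSeries, config: TrapGenConfig
) -> list[TrapObservation]:
    """Sample per-trap interval catches whose expectation follows the true curve.

    Expected cumulative proportion at each collection date is the true curve
    evaluated at degree-days accumulated under the true model; interval
    expectations are successive differences, with the post-season remainder
    folded into the final interval so the expected proportions sum to one.
    """
    acc = accumulate(weather, config.true_params)
    dd10 = dd_at_proportion(config.true_curve, 0.10)
    if date_at_dd(acc, dd10) is None:
        raise ValueError(
            f"true 10% degree-day target ({dd10:.0f}) not reached in "
            f"{weather.site_id} {weather.year}; use a warmer weather config"
        )
    rng = np.random.default_rng(config.seed)
    year_start = dt.date(weather.year, 1, 1)
    obs_dates = [year_start + dt.timedelta(days=j - 1) for j in _observation_days(config)]
    D = np.array([acc.dd_on(date) for date in obs_dates])
    cum_p = np.where(D > 0, predict_proportion(config.true_curve, np.maximum(D, 1e-9)), 0.0)
    interval_p = np.diff(np.concatenate([[0.0], cum_p]))
    interval_p[-1] += 1.0 - cum_p[-1]  # terminal remainder

    total = int(round(config.season_total))
    if config.count_noise == "multinomial":
        counts = rng.multinomial(total, interval_p)
    else:
        counts = rng.poisson(total * interval_p)

    observations: list[TrapObservation] = []
    trap_ids = [f"T{j + 1}" for j in range(config.n_traps)]
    for date, count in zip(obs_dates, counts):
        split = rng.multinomial(int(count), np.full(config.n_traps, 1.0 / config.n_traps))
        for trap_id, q in zip(trap_ids, split):
            observations.append(
                TrapObservation(
                    site_id=weather.site_id, date=date, trap_id=trap_id,
                    quantity=float(q),
                )
            )
    return observations


@dataclass
class StudySiteYear:
    """One generated site-year with its role in the development/validation split."""

    site_id: str
    year: int
    role: str  # "development" | "validation"
    weather: WeatherSeries
    observations: list[TrapObservation]

    @property
    def curve(self):
        return build_curve(self.observations, year=self.year)


def generate_study(
    n_dev: int,
    n_val: int,
    seed: int = 0,
    weather_config: WeatherGenConfig | None = None,
    trap_config: TrapGenConfig | None = None,
    site_mean_jitter_sd: float = 1.0,
    peak_day_jitter_sd: float = 5.0,
    years: tuple[int, ...] = (2019, 2020, 2021),
    out_dir: str | Path | None = None,
) -> list[StudySiteYear]:
    """Generate a development/validation study of synthetic site-years.

    Each site-year perturbs the base climate (annual mean and seasonal peak
    day) to create site-to-site phenology variation; weekly collection is
    used for 2020 site-years and twice-weekly otherwise, mirroring a typical
    field protocol.  With ``out_dir`` set, per-site-year weather and trap
    CSVs plus a YAML manifest consumable by the pipeline are written.
    """
    if n_dev < 1 or n_val < 1:
        raise ValueError("need at least one development and one validation site-year")
    base_w = weather_config or WeatherGenConfig()
    base_t = trap_config or TrapGenConfig()
    master = np.random.default_rng(seed)

    entries: list[StudySiteYear] = []
    roles = ["development"] * n_dev + ["validation"] * n_val
    for idx, role in enumerate(roles):
        tag = "DEV" if role == "development" else "VAL"
        ordinal = idx if role == "development" else idx - n_dev
        site_id = f"{tag}{ordinal + 1}"
        year = years[idx % len(years)]
        w_seed, t_seed = master.integers(0, 2**31 - 1, size=2)
        wcfg = replace(
            base_w,
            annual_mean=base_w.annual_mean + master.normal(0.0, site_mean_jitter_sd),
            peak_day=int(round(base_w.peak_day + master.normal(0.0, peak_day_jitter_sd))),
            seed=int(w_seed),
        )
        interval = 7.0 if year == 2020 else base_t.obs_interval
        tcfg = replace(base_t, obs_interval=interval, seed=int(t_seed))
        weather = generate_weather(wcfg, year, site_id=site_id)
        observations = generate_trap_catch(weather, tcfg)
        entries.append(
            StudySiteYear(site_id=site_id, year=year, role=role,
                          weather=weather, observations=observations)
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {"seed": int(seed), "site_years": []}
        for e in entries:
            stem = f"{e.site_id}_{e.year}"
            wpath = out_dir / f"{stem}_weather.csv"
            tpath = out_dir / f"{stem}_trap.csv"
            write_weather_csv(e.weather, wpath)
            write_trap_csv(e.observations, tpath)
            manifest["site_years"].append(
                {
                    "site_id": e.site_id,
                    "year": int(e.year),
                    "weather": wpath.name,
                    "trap": tpath.name,
                    "role": e.role,
                }
            )
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return entries
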