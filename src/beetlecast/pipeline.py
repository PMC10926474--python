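"""Study manifest handling and the end-to-end pipeline.

A study manifest (YAML) lists site-year weather and trap CSVs with their
development/validation roles, optional grid overrides and an output
directory.  ``run_pipeline`` executes curves → grid search → validation and
writes four artifacts: a ranked-candidate CSV, a selection JSON, a hold-out
validation CSV, and a percentile degree-day forecast table.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .degree_days import DegreeDayParams
from .emergence import dd_at_proportion
from .selection import CandidateResult, GridSpec, SelectionReport, grid_search
from .trap import SiteYearCurve, build_curve, read_trap_csv
from .validation import ValidationStats, validate
from .weather import WeatherSeries, celsius_to_fahrenheit, read_weather_csv

__all__ = ["StudyManifest", "ManifestEntry", "run_pipeline", "percentile_table"]

log = logging.getLogger("beetlecast")

FORECAST_PROPORTIONS = (0.10, 0.25, 0.50, 0.75, 0.90)


@dataclass
class ManifestEntry:
    site_id: str
    year: int
    weather_path: Path
    trap_path: Path
    role: str


@dataclass
class StudyManifest:
    entries: list[ManifestEntry]
    grid: GridSpec = field(default_factory=GridSpec)
    unit: str = "celsius"
    seed: int | None = None

    @classmethod
    def load(cls, path) -> "StudyManifest":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        entries = []
        for item in raw.get("site_years", []):
            entry = ManifestEntry(
                site_id=str(item["site_id"]),
                year=int(item["year"]),
                weather_path=path.parent / item["weather"],
                trap_path=path.parent / item["trap"],
                role=item.get("role", "development"),
            )
            for p in (entry.weather_path, entry.trap_path):
                if not p.exists():
                    raise FileNotFoundError(f"manifest references missing file: {p}")
            entries.append(entry)
        if not any(e.role == "development" for e in entries):
            raise ValueError("manifest has no development site-years")
        grid_kwargs = {}
        for key in ("lower_f", "upper_f"):
            if key in raw.get("grid", {}):
                grid_kwargs[key] = tuple(raw["grid"][key])
        if "methods" in raw.get("grid", {}):
            grid_kwargs["methods"] = tuple(raw["grid"]["methods"])
        if "start_dates" in raw.get("grid", {}):
            grid_kwargs["start_dates"] = tuple(
                tuple(s) if isinstance(s, (list, tuple)) else int(s)
                for s in raw["grid"]["start_dates"]
            )
        return cls(
            entries=entries,
            grid=GridSpec(**grid_kwargs),
            unit=raw.get("unit", "celsius"),
            seed=raw.get("seed"),
        )

    def load_data(self):
        dev, val = [], []
        for e in self.entries:
            series = read_weather_csv(
                e.weather_path, unit=self.unit, site_id=e.site_id, year=e.year
            )
            curve = build_curve(read_trap_csv(e.trap_path), year=e.year)
            pair = (series, curve)
            (dev if e.role == "development" else val).append(pair)
        return dev, val


def _biofix_label(biofix) -> str:
    if isinstance(biofix, int):
        return f"doy-{biofix}"
    return f"{biofix[0]:02d}-{biofix[1]:02d}"


def percentile_table(candidate: CandidateResult) -> pd.DataFrame:
    """Degree-day forecasts at the standard trap-catch percentiles.

    °C values are rounded to integers for presentation; the °F column is
    exactly °C × 9/5 before rounding.
    """
    rows = []
    for p in FORECAST_PROPORTIONS:
        dd_c = dd_at_proportion(candidate.fit.curve, p)
        rows.append(
            {"proportion": p, "dd_celsius": round(dd_c), "dd_fahrenheit": round(dd_c * 9 / 5)}
        )
    return pd.DataFrame(rows)


def ranked_frame(report: SelectionReport, top: int | None = None) -> pd.DataFrame:
    """Ranked candidates as a table of thresholds, method, start, AIC, CCC."""
    rows = []
    for c in report.ranked[: top or len(report.ranked)]:
        rows.append(
            {
                "lower_c": round(c.params.thresholds.lower, 1),
                "upper_c": round(c.params.thresholds.upper, 1),
                "method": c.params.method,
                "start": _biofix_label(c.params.biofix),
                "aic": round(c.fit.aic, 3) if c.fit else np.nan,
                "ccc": round(c.agreement.ccc, 3) if c.agreement else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(manifest: StudyManifest, out_dir, p: float = 0.10) -> dict:
    """Execute the full study: curves → grid search → validation → artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = dt.datetime.now()

    dev, val = manifest.load_data()
    log.info("loaded %d development and %d validation site-years", len(dev), len(val))
    log.info("evaluating %d grid candidates", manifest.grid.size)
    report = grid_search(dev, manifest.grid, p=p)
    sel = report.selected
    log.info(
        "selected %s lower=%.1f upper=%.1f start=%s (CCC=%.3f, AIC=%.2f) in %s",
        sel.params.method, sel.params.thresholds.lower, sel.params.thresholds.upper,
        _biofix_label(sel.params.biofix), sel.agreement.ccc, sel.fit.aic,
        dt.datetime.now() - t0,
    )

    ranked_path = out_dir / "ranked_candidates.csv"
    ranked_frame(report).to_csv(ranked_path, index=False)

    selection = {
        "seed": manifest.seed,
        "selected": {
            "method": sel.params.method,
            "lower_c": sel.params.thresholds.lower,
            "upper_c": sel.params.thresholds.upper,
            "start": _biofix_label(sel.params.biofix),
            "slope": sel.fit.curve.slope,
            "intercept": sel.fit.curve.intercept,
            "aic": sel.fit.aic,
            "ccc": sel.agreement.ccc,
            "precision_r": sel.agreement.precision,
            "accuracy_A": sel.agreement.accuracy,
            "dd10": sel.dd10,
        },
        "aic_rank_of_selected": report.aic_rank_of_selected,
        "n_candidates": len(report.ranked),
    }
    selection_path = out_dir / "selection.json"
    selection_path.write_text(json.dumps(selection, indent=2))

    forecast_path = out_dir / "percentile_forecast.csv"
    percentile_table(sel).to_csv(forecast_path, index=False)

    artifacts = {
        "ranked": ranked_path,
        "selection": selection_path,
        "forecast": forecast_path,
    }

    if val:
        stats = validate(sel, val, p=p)
        detail = pd.DataFrame(
            stats.per_site_year, columns=["site", "year", "predicted", "observed"]
        )
        detail["error_days"] = detail["predicted"] - detail["observed"]
        detail_path = out_dir / "validation_detail.csv"
        detail.to_csv(detail_path, index=False, float_format="%.1f")
        summary = pd.DataFrame(
            [
                {
                    "n": stats.n,
                    "mean_error": stats.mean_error,
                    "std_dev": stats.std_dev,
                    "min_error": stats.min_error,
                    "max_error": stats.max_error,
                    "ccc": stats.agreement.ccc if stats.agreement else np.nan,
                    "precision_r": stats.agreement.precision if stats.agreement else np.nan,
                    "accuracy_A": stats.agreement.accuracy if stats.agreement else np.nan,
                }
            ]
        )
        summary_path = out_dir / "validation_summary.csv"
        summary.to_csv(summary_path, index=False, float_format="%.3f")
        artifacts["validation_detail"] = detail_path
        artifacts["validation_summary"] = summary_path
        log.info(
            "validation: mean error %.1f d (sd %.1f), CCC=%.3f over %d site-years",
            stats.mean_error, stats.std_dev,
            stats.agreement.ccc if stats.agreement else float("nan"), stats.n,
        )
    return artifacts
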