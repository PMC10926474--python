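"""Hold-out validation of a selected degree-day model.

Applies the selected candidate (its degree-day parameters and fitted
emergence curve) to independent site-years and summarises the prediction
errors for the target trap-catch proportion: predicted minus observed days
(negative = model early), together with Lin's concordance between the
predicted and observed dates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .degree_days import date_at_dd, accumulate
from .emergence import dd_at_proportion
from .selection import AgreementStats, CandidateResult, concordance
from .trap import SiteYearCurve, observed_date_at_proportion
from .weather import WeatherSeries

__all__ = ["ValidationStats", "validate"]


@dataclass
class ValidationStats:
    """Summary of predicted-vs-observed dates on hold-out site-years.

    Errors are in days, predicted − observed; ``std_dev`` is the sample
    (n − 1) standard deviation.
    """

    mean_error: float
    std_dev: float
    min_error: float
    max_error: float
    agreement: AgreementStats | None
    per_site_year: list[tuple[str, int, float, float]]

    @property
    def n(self) -> int:
        return len(self.per_site_year)


def validate(
    selected: CandidateResult,
    holdout: Sequence[tuple[WeatherSeries, SiteYearCurve]],
    p: float = 0.10,
) -> ValidationStats:
    """Evaluate the selected model's date predictions on hold-out site-years."""
    if selected.fit is None:
        raise ValueError("selected candidate carries no fitted curve")
    dd_target = dd_at_proportion(selected.fit.curve, p)

    rows: list[tuple[str, int, float, float]] = []
    for series, curve in holdout:
        acc = accumulate(series, selected.params)
        pred = date_at_dd(acc, dd_target)
        if pred is None:
            warnings.warn(
                f"{curve.site_id} {curve.year}: degree-day target "
                f"{dd_target:.1f} not reached; site-year excluded",
                stacklevel=2,
            )
            continue
        obs = observed_date_at_proportion(curve, p)
        rows.append((curve.site_id, curve.year, float(pred), float(obs)))

    if not rows:
        raise ValueError("no usable hold-out site-years")
    errors = np.array([r[2] - r[3] for r in rows])
    agreement = None
    if len(rows) >= 2:
        agreement = concordance([r[2] for r in rows], [r[3] for r in rows])
    return ValidationStats(
        mean_error=float(errors.mean()),
        std_dev=float(errors.std(ddof=1)) if len(errors) > 1 else float("nan"),
        min_error=float(errors.min()),
        max_error=float(errors.max()),
        agreement=agreement,
        per_site_year=rows,
    )
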