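"""Log-logistic emergence curve: fitting, evaluation, inversion, group tests.

The cumulative proportion of seasonal trap-catch is modelled as a logistic
function of the natural log of accumulated degree-days ``D``::

    p(D) = exp(s·ln D + i) / (1 + exp(s·ln D + i))

with slope ``s`` and intercept ``i``.  The fit maximises the unit-weight
Bernoulli-form log-likelihood

    ℓ = Σ_k [ y_k·ln p̂_k + (1 - y_k)·ln(1 - p̂_k) ]

over one row per site-year × observation date, where ``y`` is the observed
cumulative proportion (possibly exactly 0 or 1, which contribute only their
defined terms).  This is the estimating problem of a binomial-family GLM
with unit weights; the optimiser is iteratively reweighted least squares
(Newton on the canonical link) with step-halving.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "EmergenceCurve",
    "FitResult",
    "CovariateTestResult",
    "FitError",
    "predict_proportion",
    "dd_at_proportion",
    "fit_log_logistic",
    "site_year_covariate_test",
]


class FitError(RuntimeError):
    """Raised when the likelihood optimisation fails to converge."""


@dataclass(frozen=True)
class EmergenceCurve:
    """Slope and intercept of the log-logistic emergence curve (both on the
    ln(°C-days) logit scale, dimensionless)."""

    slope: float
    intercept: float


@dataclass(frozen=True)
class FitResult:
    curve: EmergenceCurve
    n_obs: int
    log_likelihood: float
    aic: float
    deviance: float
    residual_df: int


@dataclass(frozen=True)
class CovariateTestResult:
    f_statistic: float
    df_numerator: int
    df_denominator: int
    p_value: float


def predict_proportion(curve: EmergenceCurve, D):
    """Cumulative emergence proportion at accumulated degree-days ``D > 0``."""
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ValueError("degree-days must be > 0")
    eta = curve.slope * np.log(D) + curve.intercept
    out = expit(eta)
    return float(out) if out.ndim == 0 else out


def dd_at_proportion(curve: EmergenceCurve, p) -> float:
    """Degree-days at which the curve reaches proportion ``p`` (exact inverse)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must be in (0, 1)")
    if curve.slope == 0:
        raise ValueError("slope must be nonzero to invert the curve")
    out = np.exp((logit(p) - curve.intercept) / curve.slope)
    return float(out) if out.ndim == 0 else out


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # y·ln p + (1-y)·ln(1-p) = y·eta - log(1 + e^eta), stable for any eta,
    # and exact-0/1 observations contribute only their defined terms.
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _saturated_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    # binomial deviance relative to the saturated model p̂ = y (0·ln 0 = 0)
    from scipy.special import xlogy

    return float(2.0 * np.sum(xlogy(y, y) - xlogy(y, mu)
                              + xlogy(1 - y, 1 - y) - xlogy(1 - y, 1 - mu)))


def _fit_logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float]:
    """Maximise the Bernoulli-form log-likelihood over ``X @ beta``.

    Deterministic initialisation from the least-squares line of empirical
    logits (y clamped to [0.005, 0.995] for initialisation only), then IRLS
    with step-halving when a step would decrease the likelihood.
    """
    z0 = logit(np.clip(y, 0.005, 0.995))
    beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    ll = _bernoulli_ll(y, X @ beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        try:
            step_beta = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular weighted design: {exc}") from exc
        # step-halving: fall back toward the current iterate if needed
        direction = step_beta - beta
        factor = 1.0
        for _half in range(30):
            candidate = beta + factor * direction
            ll_new = _bernoulli_ll(y, X @ candidate)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-14:
                break
            factor *= 0.5
        else:
            raise FitError("step-halving failed to find an uphill step")
        delta = abs(-2.0 * ll_new - (-2.0 * ll))
        beta, ll = candidate, ll_new
        if delta < tol:
            return beta, ll
    raise FitError(
        f"IRLS did not converge in {max_iter} iterations "
        f"(last deviance change {delta:.3e})"
    )


def fit_log_logistic(points: Sequence[tuple[float, float]]) -> FitResult:
    """Fit the emergence curve to pooled ``(D, y)`` points.

    Requires at least three points, all with ``D > 0``, and non-constant
    ``y``.  Returns the fitted curve together with the log-likelihood,
    deviance (−2ℓ) and AIC (2k − 2ℓ with k = 2 fitted parameters).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (D, y) pairs")
    if len(pts) < 3:
        raise ValueError(f"need at least 3 points, got {len(pts)}")
    D, y = pts[:, 0], pts[:, 1]
    if np.any(D <= 0):
        raise ValueError("all degree-day values must be > 0")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if np.all(y == y[0]):
        raise ValueError("all proportions identical; curve not identifiable")
    X = np.column_stack([np.ones_like(D), np.log(D)])
    beta, ll = _fit_logistic_irls(X, y)
    k = 2
    return FitResult(
        curve=EmergenceCurve(slope=float(beta[1]), intercept=float(beta[0])),
        n_obs=len(pts),
        log_likelihood=ll,
        aic=2.0 * k - 2.0 * ll,
        deviance=-2.0 * ll,
        residual_df=len(pts) - k,
    )


def site_year_covariate_test(
    groups: Mapping[object, Sequence[tuple[float, float]]],
    which: str = "intercept",
) -> CovariateTestResult:
    """F-test for a site-year effect on the intercept or the degree-day slope.

    Compares the pooled two-parameter fit (reduced) against a model with
    group-specific intercepts (``which="intercept"``) or group-specific
    slopes on ln D (``which="slope"``) via the deviance-based F statistic

        F = [(Dev_reduced − Dev_full) / Δdf] / [Dev_full / df_full]

    where Dev is the binomial deviance relative to the saturated model
    (p̂ = y); the saturated terms cancel in the numerator, while the
    denominator then estimates the residual dispersion, which is what makes
    the statistic approximately F-distributed under the null for
    proportion-valued observations.
    """
    if which not in ("intercept", "slope"):
        raise ValueError("which must be 'intercept' or 'slope'")
    keys = list(groups)
    if len(keys) < 2:
        raise ValueError("need at least 2 groups")
    for key in keys:
        if len(groups[key]) < 2:
            raise ValueError(f"group {key!r} has fewer than 2 points")

    D, y, labels = [], [], []
    for gi, key in enumerate(keys):
        for d, prop in groups[key]:
            D.append(d)
            y.append(prop)
            labels.append(gi)
    D = np.asarray(D, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    if np.any(D <= 0):
        raise ValueError("all degree-day values must be > 0")
    logD = np.log(D)
    n = len(y)
    G = len(keys)

    X_red = np.column_stack([np.ones(n), logD])
    dummies = (labels[:, None] == np.arange(G)[None, :]).astype(float)
    if which == "intercept":
        X_full = np.column_stack([dummies, logD])
    else:
        X_full = np.column_stack([np.ones(n), dummies * logD[:, None]])
    k_full = X_full.shape[1]

    beta_red, _ = _fit_logistic_irls(X_red, y)
    beta_full, _ = _fit_logistic_irls(X_full, y)
    dev_red = _saturated_deviance(y, expit(X_red @ beta_red))
    dev_full = _saturated_deviance(y, expit(X_full @ beta_full))

    df_num = G - 1
    df_den = n - k_full
    if df_den <= 0:
        raise ValueError("full model has no residual degrees of freedom")
    f_stat = max(0.0, (dev_red - dev_full) / df_num) / (dev_full / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    return CovariateTestResult(
        f_statistic=float(f_stat),
        df_numerator=df_num,
        df_denominator=df_den,
        p_value=p,
    )
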