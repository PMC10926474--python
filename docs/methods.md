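# Methods

## Degree-day calculations

Both daily calculations clamp at the upper threshold with a **horizontal
cutoff**: temperature above T_U contributes as if it were exactly T_U, and
heat above the optimum is never subtracted. The simple average method is
"method 1": the observed extremes are averaged *without* pre-clamping to
T_L, so a freezing night can cancel a warm afternoon; the capped average
minus T_L, floored at zero, is the daily value. Daily values therefore lie
in [0, T_U − T_L] for both methods.

The sine-wave method models each half day as `T(θ) = m + α·sin θ` over
`θ ∈ [−π/2, π/2]` with midpoint `m` and amplitude `α` taken from the
half-day's two extremes, and accumulates the thresholded area
`(1/2π)∫ max(0, min(T(θ), T_U) − T_L) dθ`. The closed form has six branches
(fully below, fully above, fully between, crossing T_L, crossing T_U,
crossing both); a seeded 1,000-case property test holds every branch to
within 1e-6 °C-days of direct numerical quadrature, which is treated as the
authoritative definition. The default convention is the double-sine one:
the falling half day descends from today's maximum to *tomorrow's* minimum
(the last day reuses its own minimum); a switch (`double_sine=False`) uses a
single day's extremes for both halves. When the following minimum exceeds
the day's maximum the falling half day is flat at the maximum.

Biofix dates are stored as calendar (month, day) and resolved per year, so
Mar 1 is day-of-year 60 or 61 depending on leap year; an integer biofix is
also accepted and applied as a literal day-of-year in every year (the grid
module exposes `LITERAL_JULIAN_START_DATES = (1, 32, 50, 91)` for that
mode). `date_at_dd` places the crossing of a degree-day target linearly
within the crossing day by default, with a first-whole-day (ceiling) mode
behind a flag; a target beyond the season total returns `None` rather than
raising, so callers can distinguish "not reached" from invalid input.

## Trap-catch reduction

Traps are pooled by summation within site and collection date. Proportions
are identical to trap-averaging when every trap is observed on every date,
and pooling degrades gracefully when one trap is missing. Quantities may be
beetle counts or volumetric measurements; only the cumulative proportion of
the season total enters the model. Observed dates at a target proportion are
interpolated linearly on the calendar-day axis between the bracketing
observations (degree-day-axis interpolation is available by passing an
accumulation series); when the first observation already exceeds the target
the first date is returned with a left-censoring warning.

## Emergence model and likelihood

The dependent variable is the per-observation-date cumulative proportion
with unit weight — one row per site-year × date — not count-weighted
binomial trials. The fit maximizes ℓ = Σ [y·ln p̂ + (1−y)·ln(1−p̂)] with p̂
from the log-logistic curve in ln D; exact 0 and 1 observations contribute
only their defined terms (the likelihood is evaluated as
`y·η − log(1+e^η)`, which is stable for any linear predictor η). The
optimizer is IRLS (Newton on the canonical link) with step-halving,
initialized deterministically from the least-squares line of empirical
logits (y clamped to [0.005, 0.995] for initialization only), converging at
|Δdeviance| < 1e-10 within 100 iterations. AIC counts k = 2 parameters and
no dispersion. A binomial-family GLM solves the same estimating equations,
and the test suite cross-checks the coefficients against statsmodels to
1e-6; the log-likelihood *constant* differs for fractional y, which is why
the fit is computed in-house.

The site-year covariate F-test compares the pooled fit against group-specific
intercepts (or group-specific ln D slopes) using the **saturated-relative**
binomial deviance in the F ratio,
`F = [(Dev_red − Dev_full)/Δdf] / [Dev_full/df_full]`. The saturated terms
cancel in the numerator, so only the denominator depends on this choice —
and it must: the raw −2ℓ of fractional proportions contains the intrinsic
entropy of y, which would inflate the denominator and drive F toward zero.
With the saturated-relative form a Monte-Carlo null simulation (binomial
proportion noise) shows the α = 0.05 rejection rate inside the binomial
confidence band, which is the calibration the test is designed to have.

## Grid search and selection

The threshold lattice is specified in °F (lower 32–59, upper 68–100, 1 °F
steps) and converted to °C for computation; with four start dates and two
methods this yields exactly 28 × 33 × 4 × 2 = 7,392 candidates in
deterministic (method, start date, lower, upper) order. Each candidate is
evaluated by accumulating degree-days per development site-year, pooling
(D, y) points (observation dates with D ≤ 0 are dropped — their log
transform is undefined and they carry no thermal signal), fitting the
emergence curve, inverting it at p = 0.10, and scoring predicted against
observed 10% dates with Lin's CCC (population-moment form, decomposed as
r × A). Pooled points are sorted before fitting so results are bit-identical
under any site-year ordering. Candidates whose degree-day target is not
reached in ≥ n−1 site-years, or whose point cloud cannot be fitted (or fits
with a non-positive slope), are marked unscorable and rank below all
scorable candidates. Selection sorts by CCC descending, then AIC ascending,
then enumeration order, and also reports the winner's ordinal rank by AIC
alone. Daily degree-day arrays are cached per (method, thresholds,
site-year), so the four start dates sharing a threshold pair reuse one
computation; the full search over six site-years takes ~15 s on one CPU.

Validation applies the winner's parameters and fitted curve to hold-out
site-years; errors are predicted − observed in days (negative = model
early), summarized with the sample (n−1) standard deviation and the CCC
decomposition.

## Synthetic data generator

The generator emulates a temperate (Minnesota-like) climate: daily mean
`annual_mean + seasonal_amplitude · sin(2π(d − peak_day + 91.25)/365.25)`
plus AR(1) noise (lag-1 coefficient 0.6, Normal innovations, initialized
from the stationary distribution), with constant diurnal range split evenly
around the mean. Defaults — annual mean 7 °C, amplitude 16 °C, peak day
200, diurnal range 10 °C, innovation sd 3 °C — put the 10% trap-catch date
in late June–July under the default true model. The AR(1) structure matters:
correlated warm spells create the multi-day accumulation bursts that stress
within-day interpolation of crossing dates.

Trap-catch counts are sampled per collection date: expected cumulative
proportion is the true emergence curve evaluated at degree-days accumulated
under the true model, interval expectations are successive differences with
the post-season remainder folded into the final interval, counts are drawn
multinomially with the configured season total (or as independent Poissons)
and split uniformly across four trap ids. Collections run twice weekly from
day 166 through day 272 (weekly for 2020 site-years, mirroring a typical
pandemic-constrained protocol). Studies jitter each site-year's annual mean
(sd 1 °C) and seasonal peak (sd 5 d) to create site-to-site phenology
variation, and cycle site-years through 2019–2021. All randomness flows
from one top-level seed through `numpy.random.default_rng`.

What the generator does *not* emulate: trap saturation and lure-decay
effects, within-site trap heterogeneity, immigration pulses, volumetric
rounding, weather-station measurement error, and any dependence of catch on
weather beyond the thermal-accumulation pathway. Passing recovery tests
therefore demonstrate that the pipeline is a consistent estimator under its
own model assumptions, not that the fitted thresholds transfer to field
data. One realistic artifact is deliberately retained: the simulated season
captures only ~96% of the theoretical emergence mass (as real trapping
seasons do), and renormalizing to the observed season total inflates
recovered slopes by roughly 1–2%. A related identifiability note: the CCC
surface is nearly flat within a grid step or two of the true thresholds,
because adjacent thresholds rescale the degree-day axis almost linearly —
the selected cell can land a step away from truth while the recovered
phenology dates are essentially exact; degree-day targets are therefore
only comparable between models sharing the same thresholds.

## Problem sizes and numerical choices

The test suite runs the full 7,392-candidate search on a 6+6 site-year
synthetic study (seed 0) plus reduced grids elsewhere; the Monte-Carlo
calibration of the covariate test uses 400 null replicates of 4 groups × 12
binomial-proportion observations. Weather I/O rejects gaps by default and
can fill runs of ≤ 3 missing days by linear interpolation of the extremes
separately. Degenerate flat half-days (α = 0) accumulate
`0.5·max(0, min(m, T_U) − T_L)`. Concordance uses population (1/n) moments
and raises on zero variance or zero correlation rather than defining the
accuracy factor arbitrarily.
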