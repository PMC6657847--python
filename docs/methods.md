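# Methods

This note documents the models, numerical choices, and synthetic-data
design behind `overwinter`, in the order the pipeline runs.

## Daily series and gap handling

A `DailySeries` is a calendar-day temperature vector with a per-day
provenance tag (source name, `interpolated`, `predicted`, `missing`).
Merging takes, per day, the first source in priority order that carries
a value.  Sub-daily records are assumed to be averaged to one value per
day upstream of ingestion.

Interior missing runs are filled by the straight line between the
flanking observations evaluated at integer day offsets.  This is
defensible for water temperature because day-to-day anomalies persist
for weeks (high specific heat), so a gap of several days carries little
unresolved signal.  Leading and trailing missing runs are trimmed, not
extrapolated — extrapolation has no support in the data.  `max_gap`
(default unlimited) leaves longer runs missing with a logged warning so
a caller can treat severe outages differently.

Gap statistics (count, mean and maximum run length, missing fraction)
are defined on the *raw* record, between its first and last observed
day, because they describe the observing process, not the filled
product.

The **decorrelation scale** is the smallest positive lag at which the
sample autocorrelation falls below 1/e.  Two variants exist because the
criterion is ambiguous in practice: the default retains the seasonal
cycle (the scale is then set mostly by the annual harmonic's arccos
geometry), and `deseasonalize=True` first removes a fitted
trend-plus-annual-harmonic so the scale describes the persistence of
day-to-day anomalies.  For a persistent series the sample estimate
scatters by roughly ±10–25 days between realisations; single values
should be read accordingly.

## Harmonic model and transfer function

The temperature model is

    T(t) = B0 + B1·t + Σ_{m=1..M} [C_m cos(m·w·t) + S_m sin(m·w·t)],
    w = 2π/365.25 per day.

The time coordinate t is continuous days since a declared origin
(default 1938-01-01).  A day-of-year-only mode exists as a degraded
option for pure seasonal climatology; it cannot carry a multi-decade
trend, which is why continuous time is the default.  M defaults to 1
(annual cycle); higher harmonics are configurable.  Fits require at
least two full annual cycles — with less data the trend and the annual
harmonic are confounded.

Point estimates are ordinary least squares.  Coefficient standard
errors default to Newey–West (HAC) with a 182-day Bartlett window:
daily temperature residuals are strongly autocorrelated, and classical
OLS standard errors understate the sampling error several-fold (the
inflation is ≈ √((1+φ)/(1−φ)) for AR(1) residuals at low frequency —
roughly 3× at φ ≈ 0.8 and worse beyond).  With HAC errors the
propagated 2-SE interval on a transfer ratio covers the truth in
97–98 of 100 synthetic replicates; with classical errors, 27 of 100.
`cov_type="nonrobust"` restores the classical covariance.

The calibration protocol samples 30% of observed days uniformly without
replacement, fits air and water on that subset, forms the per-harmonic
ratios `cr_m = CW_m/CA_m`, `sr_m = SW_m/SA_m` (first-order error
propagation, no cross-fit covariance), and reports RMSE on the 70%
holdout.  The final transfer function refits both series on all days
and rebuilds the ratios; the calibration/validation stage is kept only
for the RMSE comparison.  Air harmonic coefficients within 1e-6 °C of
zero reject the ratio as undefined.  A ~zero air trend yields
trend_ratio 1 when the water trend is also ~zero (identity case) and
NaN with a warning otherwise.

**Prediction modes.**  `predict_water` evaluates
`WT(t) = B0 + B1·t + Σ cr_m CA_m cos + sr_m SA_m sin` with two
intercept/trend conventions:

* `literal` — B0, B1 from the water-side fit.  Used when reproducing or
  extending the record the transfer was built on (the extended-trend
  scenario), where the observed water trend is the trend.
* `inherit_trend` — B1 = trend_ratio × (driving air fit's B1), with B0
  offset so the non-seasonal part of the prediction matches the fitted
  water record at a junction date.  Used when the driving air series
  carries its own warming (climate-model members).  The default
  junction is the **midpoint of the trailing 30-year climatology
  window**: the prediction then agrees with the recently observed
  climate on average — the role bias correction plays for downscaled
  model output — while the member's own (typically faster) warming
  operates beyond it.  Anchoring at the final observed day instead
  would silently discard the extra warming a high-emissions member
  accumulates during the historical overlap and delay the divergence of
  the scenarios by decades.

## Projections and uncertainty

`extend_trend` evaluates the literal prediction from the day after the
last observation to the requested end date; it is deterministic, so
projected winters vary only through the trend and the leap-day
artifact.  Uncertainty comes from `resample_projections`: each member
redraws every coefficient (water B0 and B1, air harmonic coefficients,
transfer ratios) independently from Normal(estimate, SD) and
re-evaluates the projection; the ensemble is summarised by per-day mean
and sample SD.  Ignoring coefficient covariances understates joint
uncertainty somewhat; with HAC SDs the resulting end-of-century daily
SD is a few tenths of a degree.

`read_member_ensemble` converts per-member daily min/max over grid
cells to one air series per member (midpoint (min+max)/2, unweighted
mean over cells).  Days with min > max are rejected with a warning;
members missing more than 5% of days are dropped.  `project_ensemble`
refits the harmonic model per member (whole span by default; an
optional fixed-length-window mode tracks curvature in the member's
warming piecewise), predicts water in `inherit_trend` mode, and
summarises across members.  Reported projections start the day after
the observational record ends; the overlap era is used only for
fitting.

## Winter metrics and survival

Winter years bridge calendar years and are labelled by the first: the
window is anchored July 1 – June 30, so winter 1990 runs 1990-07-01 to
1991-06-30.  Winter length is the count of days strictly below the
threshold (default 9 °C, the critical temperature for growth in blue
crab); severity is the mean temperature over those below-threshold days
(a whole-window variant is switchable, since either reading is
defensible).  Only winters fully covered by the series are emitted;
edge winters are omitted with a notice.  Leap-year windows are real
366-day windows, so a uniformly cold leap winter is exactly one day
longer — an artifact of the calendar, deliberately not patched.

Overwinter survival is the Weibull accelerated-failure-time model

    S(t) = exp(−t^λ · exp(−λ·(β0 + βT·Temp + βS·Sal + βZ·Size)))
         = exp(−(t/η)^λ),  η = exp(β0 + β·x),

with fitted juvenile-crab coefficients β0 = 3.59, βT = 0.10 /°C,
βS = 0.02 per salinity unit, βZ = 0.03 /mm, and Size defaulting to the
40 mm juvenile stage.  The shape λ and the salinity covariate come from
external sources and are **required** parameters — the package ships no
default, and survival levels reported anywhere in its output are
conditional on the supplied pair.  Each winter is scored at
t = length_days with its own severity as Temp; a zero-length winter
(no day below threshold, hence no dormancy) scores survival 1.

## Statistics

Yearly trends are plain OLS with a two-sided slope test; an exclusion
list drops unusable winters before fitting (the historical record's
1977 winter is the canonical example).  Scenario contrasts are Welch
unequal-variance t-tests per fixed interval (Student's pooled variant
and a Bonferroni flag are available; neither is the default, matching
common reporting of raw per-interval P values at α = 0.05).  Intervals
without two winters on both sides are reported as not computable.
`latitude_equivalent` regresses anchor-station days-below-threshold on
latitude, inverts at the queried winter length, refuses queries outside
the anchors' range ± 10% (extrapolation), and warns when the slope is
not significantly positive.

## Synthetic generator

The generator is the package's study-condition record: every default
was derived once from the emulated system's published summary
statistics, and the tests treat the generator's parameters — never the
pipeline's output — as truth.

* Water reference mean 15.2 °C over 1961–1990 and trend
  0.022 °C/yr (a 2.4 °C rise between the 1961–1990 and 2070–2099
  window midpoints).  Annual amplitude 12.3 °C with the seasonal peak
  near day 210, so the total daily SD is ≈ 8.9 °C once noise is added;
  air amplitude 14.5 °C peaking ~10 days earlier (air leads water),
  air reference mean 14.6 °C, trend ratio 1.
* Water anomalies are AR(1) with φ = exp(−1/91) (anomaly e-folding time
  of 91 days, the record's reported decorrelation scale) and marginal
  SD 1.5 °C; air anomalies φ = 0.95, SD 2.5 °C; innovation correlation
  0.6.  This persistence also reproduces the observed interannual
  winter-length spread (≈ ±15 days).  Note the *default* (seasonal-in)
  decorrelation definition yields ≈ 70 days on this record — the two
  definitions genuinely differ, which is why both are exposed.
* Gaps: each weekend day missing with probability 0.35, 1% random
  holidays, and Poisson-placed outages (1.5/yr, geometric lengths, mean
  8 d), giving ≈ 13–15% missingness in the raw single-station record —
  the published filled fractions.  (A deterministic all-weekends-missing
  rule would force ≥ 28.6% and contradict those fractions.)  Fallback
  stations observe independent ~50%/35% subsets of days with 0.25 °C
  instrument scatter.
* Ensemble members share the seasonal structure, are anchored to the
  observed air climatology at the reference-window midpoint, and draw
  warming rates from Normal(4.1, 1.0) °C/century.  4.1 is the rate that
  carries the reference water climatology to the high-emissions
  end-of-century mean (≈ 19.2 °C for 2070–2099) through the
  trailing-climatology anchoring above, and is consistent with
  high-emissions regional air-warming rates; the 1.0 spread yields an
  end-of-century winter-length spread of roughly ±10–20 days across
  members.

What the generator does **not** emulate: changes in seasonal amplitude
or phase under warming (members differ only in trend), skewed or
heavy-tailed daily anomalies, instrument changeovers, salinity and
ice effects, and inter-model differences in seasonal shape.  Passing
tests therefore demonstrate that the pipeline recovers what it assumes
— harmonic seasonality, linear trends, AR(1) anomalies — not that those
assumptions exhaust real estuarine records.

## Problem sizes and tolerances

The shipped tests and the acceptance script use the native problem
sizes of the emulated study: the full 79-year daily record, 50
coefficient-resampled projections, and a 41-member ensemble spanning
1950–2099 (smaller 6-year records serve the 100-replicate coverage
checks).  The whole suite runs in well under a minute.  Stochastic
assertions use closed-form oracles with bands set from the analytic
noise level of the quantity (e.g. a reference-window mean has standard
error ≈ sd·√(2τ/n) ≈ 0.19 °C under the default noise, so the band is
0.6 °C); exact identities (S(0) = 1, λ = 1 exponential equivalence,
zero-SD resampling collapse) are asserted at 1e-12.  Window-mean
identities use 1461-day (4 × 365.25) windows, over which daily-sampled
annual harmonics sum to exactly zero.

## Known limitations

* The transfer function assumes the air–water coupling (the coefficient
  ratios) is stationary under warming.
* Coefficient resampling ignores cross-coefficient covariance.
* Severity-based survival treats winters as homogeneous exposures; no
  size structure, density dependence, or spatial variation.
* Whole-span member refitting linearises any curvature in a member's
  warming; the windowed mode mitigates but does not remove this.
* OLS trend inference on yearly winter metrics ignores their serial
  correlation.
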