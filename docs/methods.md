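# Methods

This note documents the statistical procedure the package implements, the
choices made where the design was genuinely open, and what the synthetic-data
validation does and does not establish.

## First-stage model

Each location's daily death counts are fitted by a log-link Poisson GLM with
variance inflated by a dispersion parameter (quasi-Poisson). The linear
predictor contains:

- an intercept;
- a natural cubic spline of the day index with `round(8 × n_days/365.25)`
  total degrees of freedom (the per-year rate is the literature standard for
  removing seasonality and trend; the rounding rule is ours, since a per-year
  rate does not define one), knots at equally spaced quantiles of the index;
- six reference-coded day-of-week indicators (Monday reference);
- the DLNM cross-basis of temperature.

The cross-basis crosses a quadratic B-spline over temperature (internal knots
at the location's 10th/75th/90th empirical percentiles, boundary knots at the
observed min/max, intercept dropped, dimension vx = 5) with a natural cubic
spline over lags 0–21 days (with intercept, three internal knots equally
spaced on the log-lag scale anchored at log 1 — the only anchoring consistent
with a lag range that starts at 0 — dimension vl = 5). Percentiles are type-7
(linear interpolation) empirical quantiles throughout; this convention is
fixed so knot placement is reproducible.

The first 21 rows of the cross-basis only see the available history
(truncated sums) and are kept in the likelihood, flagged as edge rows, rather
than dropped: this preserves alignment with the outcome series, and at the
series lengths used here the difference is negligible. Days with missing
deaths are dropped from the likelihood with a warning; nothing is imputed.

Fitting is iteratively reweighted least squares (via statsmodels' GLM) with a
deviance tolerance of 1e-9 and at most 50 iterations; the dispersion is the
Pearson chi-square over the residual degrees of freedom, and the coefficient
covariance is scaled by it. Rank deficiency and non-convergence raise with
diagnostics rather than returning silently degraded fits.

### Reduction

Lag-response cumulation uses the integer lag grid l = 0..21 (daily data make
the sum, not an integral, the natural reading): c_k = Σ_l C_k(l),
η = (I_vx ⊗ c′)θ_cb, V_η = M V_cb M′. The reduction is exact: the reduced
curve's cumulative log-RR equals the lag-summed full-surface log-RR at every
temperature (tested to 1e-10), so nothing is lost by pooling only (η, V_η).

## Second stage

The reduced curves are pooled by multivariate random-effects meta-regression
η_i ~ N((x_i ⊗ I)β, S_i + Ψ). Default meta-predictors: intercept, country
indicators (reference-coded against the alphabetically first country),
location average temperature, and temperature range; continuous predictors
are centred and scaled internally for optimisation conditioning and the
transform undone on output, which leaves the fit invariant to the
parameterisation (tested to 1e-8 on the restricted likelihood).

Ψ is estimated by REML (ML available for likelihood-ratio comparisons) over
its Cholesky factor with log-scaled diagonal, which enforces positive
semidefiniteness without constraints. The optimiser is L-BFGS-B with the
analytic gradient of the (restricted) profile likelihood — the score
tr[(Σ_i⁻¹ − u_i u_i′ − Q_i) dΨ] mapped through the Cholesky chain rule —
objective tolerance 1e-14, gradient tolerance 1e-10, moment-based start
(residual covariance about the fixed-effects fit minus the mean S_i, eigen-
clipped to PSD), and up to five jittered restarts on failure. Heterogeneity
is summarised by the multivariate Cochran Q about the fixed-effects (Ψ = 0)
GLS fit, with I² = max(0, (Q − df)/Q) × 100; predictor effects by the
multivariate Wald statistic on the vectorised fixed effects.

BLUPs are θ̃_i = X̃_i β̂ + A_i(η_i − X̃_i β̂) with A_i = Ψ̂(S_i + Ψ̂)⁻¹, and
covariance A_i S_i A_i′ + (I − A_i) X̃_i V_β X̃_i′ (I − A_i)′, which has the
right limits (location estimate as S_i → 0, fixed-effect prediction as
Ψ̂ → 0). Each BLUP also records the decomposition of its covariance into the
shared fixed-effect part and the location-specific residual part; the Monte
Carlo step uses it (below).

## Attribution

The minimum mortality temperature is the BLUP curve's minimum over the grid
of the 1st–99th integer empirical percentiles (the restriction keeps the
reference away from unstable extremes); exact ties break toward the median
percentile. Re-centring the exposure basis at the MMT yields the daily
cumulative log-RR b_t, zero at the MMT by construction and independent of the
internal reference used during fitting.

Attribution uses the forward perspective: day t's exposure is held
responsible for AF_t = 1 − exp(−b_t) of the deaths over days t..t+21,
weighted by the mean of the death counts over that window. Windows near the
series end shrink to the available days (an option drops incomplete windows
instead); totals are sums over days, and AF = AN / total deaths. A backward
option attributes day-t deaths to the exposure history summarised by the mean
temperature over t−21..t fed through the cumulative curve — the standard
device when only the cumulative curve is available — and is provided for
sensitivity only.

Days are partitioned by their own temperature: cold/heat at the MMT (a day
exactly at the MMT carries zero attributable deaths and is counted on the
heat side), extreme/moderate within each side at the 2.5th/97.5th
percentiles. The partition is exact by construction, so cold + heat = total
and moderate + extreme = each side's total at machine precision; optional
cutoffs (10/25/50/75/90th) feed a per-percentile-band table.

### Empirical confidence intervals

eCIs are empirical 2.5th/97.5th percentiles over Monte Carlo draws of the
reduced BLUP coefficients, with each location's MMT held at its point
estimate; all randomness derives from one seed through spawned generator
streams, so results are bit-reproducible.

Draws are *joint* across locations by default: one N(0, V_β) fixed-effect
draw per simulation is propagated to every location through
(I − A_i) X̃_i, plus an independent N(0, A_i S_i A_i′) residual draw per
location. Per-location marginals are identical to independent MVN(θ̃_i, V_i)
sampling; only the cross-location correlation — which is real, since every
BLUP shares the pooled fixed-effect error — is restored. This choice was made
after simulation showed that independent draws understate pooled uncertainty
by roughly √m (coverage of the true total AF degraded from 0.89 at 6
locations to 0.83 at 10, against a nominal 0.95), whereas joint draws give
0.91–0.94 and improve with m. `resample="independent"` restores the
uncorrelated scheme for comparison.

## Synthetic-data generator

The generator emulates the structure of a multi-country daily mortality
dataset so that the whole pipeline can be validated against a known truth:

- **Temperature**: annual sinusoid (location mean, half-range 8 °C by
  default, peak in mid-July) plus AR(1) Gaussian noise (ρ = 0.6, innovation
  sd 2 °C), on a simple 365-day calendar (leap days are ignored by the
  generator; real-data ingestion handles true calendars).
- **Mortality**: log-rate = log baseline (30 deaths/day) + a mild 10%
  winter-peaking seasonal cycle + small day-of-week effects + the lagged
  temperature term Σ_l w_l f(x_{t−l}), with f linear below the true MMT
  (0.02 log-RR per °C) and quadratic above it (0.015 per °C²) — the
  asymmetric, cold-dominated shape characteristic of observed pooled
  curves — and smooth exponentially decaying lag weights summing to 1 over
  lags 0–21. The first 21 days renormalise the truncated weights rather than
  being burned in, keeping series lengths exact.
- **Counts**: gamma-Poisson (negative-binomial) with variance μ × 1.3,
  matching the first-stage mean–variance assumption at the moments level
  (quasi-Poisson has no generative form); exactly Poisson when the
  overdispersion is 1.
- **Heterogeneity**: the true MMT tracks each location's mean temperature
  one-for-one (acclimatisation; the coupling is configurable), placing it
  near the 78th percentile everywhere, and the slope/curvature coefficients
  receive N(0, 0.003²) location-level perturbations, clipped at zero.
  Countries differ in mean climate (7–24 °C in the default 4-country
  scenario), which ties the between-location structure to the
  meta-predictors.

Because the surface is separable and known, the true attributable fraction is
available in closed form on the expected-death scale, using only the
temperature term of the log-rate: AF = 1 − n / Σ_t exp(s_t) with s_t the
factual cumulative log-RR. Defined this way the truth is exactly invariant to
baseline, seasonality, and day-of-week effects (they cancel identically),
which is the correct oracle for an attribution method that is itself a ratio.
Cold/heat components of the truth classify each day's factual excess by the
day's own temperature, matching the estimator's partition semantics.

What the generator does **not** emulate: real calendars and leap days,
missing data, measurement error in exposure, multi-monitor aggregation,
cause-specific mortality, co-pollutant and humidity confounding, population
change over long periods, and lag structures that vary with temperature
(the true surface is separable). Passing recovery tests on this generator
therefore demonstrates the correctness of the estimation machinery under the
model's own assumptions, not robustness to their violation.

## Validation scales and numerical choices

The simulation-based tests run at deliberately modest sizes: end-to-end
recovery uses 50 replicates of 20 locations × 5 years (mean absolute error
of the total AF under 1 percentage point; MMT percentile within ±5, median);
eCI calibration uses 200 replicates of a scaled 6-location × 3-year scenario
with 500 draws; meta-regression recovery simulates 200 reduced-curve datasets
of 40 locations directly. Tie-breaks, tolerances, and conventions pinned for
reproducibility: type-7 quantiles, IRLS deviance tolerance 1e-9/50
iterations, REML tolerances as above, MMT ties toward the median percentile,
cached intermediates written with 17-significant-digit floats and re-read
with round-trip parsing so resumed runs are bit-identical.

## Known limitations

- **Null behaviour of the attribution reference.** Because the attribution
  reference is the argmin of the *estimated* pooled curve, the total AF at a
  true null is a positively biased max-type statistic, and its Monte Carlo
  eCI (which holds the MMT fixed and resamples coefficients only) rarely
  covers zero — in our null simulations almost never. The bias-to-spread
  ratio is scale-free, so more data does not remove it. Interpreting small
  attributable fractions therefore requires care; the curve-level CIs are
  honest (first-stage contrast coverage ≈ 95–98% at the null) even when the
  AF point estimate is not.
- MMT uncertainty is excluded from the eCIs by design (the point estimate is
  held fixed), which contributes mild undercoverage.
- The backward attribution option is an approximation built on the cumulative
  curve (mean past temperature), not a lag-specific reconstruction.
- REML covariances are anti-conservative when the number of locations barely
  exceeds the number of meta-predictors; the pipeline only enforces the
  identifiability minimum.
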