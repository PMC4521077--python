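# tempmort

Two-stage distributed-lag non-linear modelling of the mortality burden
attributable to non-optimum ambient temperature.

Environmental epidemiologists routinely ask how many deaths in a population
are advanced by days that are colder or hotter than the local optimum, and how
that burden splits between cold and heat and between moderate and extreme
temperatures. `tempmort` implements the standard two-stage answer for
multi-location daily time series (date, all-cause deaths, mean temperature),
plus a synthetic-data generator with a known risk surface so every stage of
the pipeline can be validated against an exact oracle.

## The model

**Stage 1 — per location.** Daily death counts are modelled by quasi-Poisson
regression

log E[Y_t] = α + s(t; 8 df/year) + DOW_t + Σ_{j,k} θ_{jk} Σ_{l=0}^{21} R_j(x_{t−l}) C_k(l)

where `s` is a natural cubic spline of time (seasonality and trend), `DOW` are
day-of-week indicators, and the last term is the DLNM cross-basis: a quadratic
B-spline over temperature `R` (knots at the location's 10th/75th/90th
percentiles, vx = 5) crossed with a natural cubic spline over lag `C`
(intercept + 3 knots equally spaced in log-lag over 0–21 days, vl = 5). Each
fit is *reduced* by cumulating the lag dimension: with c_k = Σ_l C_k(l),

η = (I ⊗ c′) θ,  V_η = (I ⊗ c′) V_θ (I ⊗ c′)′

giving a 5-coefficient *overall cumulative exposure–response curve* per
location.

**Stage 2 — pooling.** The η_i are pooled by multivariate random-effects
meta-regression, η_i ~ N(X_i β, S_i + Ψ), with country indicators, average
temperature, and temperature range as meta-predictors; Ψ is estimated by REML.
Residual heterogeneity is reported by the multivariate Cochran Q and I², and
predictor effects by multivariate Wald tests. Best linear unbiased predictions
(BLUPs) shrink each location's curve towards its meta-regression prediction.

**Attribution.** The minimum mortality temperature (MMT) is the BLUP curve's
minimum over the 1st–99th integer temperature percentiles. Re-centring the
curve at the MMT gives a daily cumulative log relative risk b_t; under the
forward perspective a day's exposure is responsible for a fraction
1 − exp(−b_t) of the deaths over the next 21 days, so

AN = Σ_t (1 − exp(−b_t)) · mean(Y_{t..t+21}),  AF = AN / Σ_t Y_t.

Components (cold/heat at the MMT; moderate/extreme at the 2.5th/97.5th
percentiles) partition the total exactly. 95% empirical CIs come from Monte
Carlo resampling of the BLUP coefficients (jointly across locations through
the shared fixed effects), with the MMT held at its point estimate.

This mirrors the methodology of the large multi-country temperature–mortality
literature (the 13-country, 384-location analysis of 74 225 200 deaths whose
country descriptives ship in `tempmort.reference`). The registry data
themselves are not public, so the package validates on synthetic data with a
known surface instead of reproducing those published estimates.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic data
(20 locations, 4 countries, 5 years each, overdispersion 1.3, a V-shaped
cumulative exposure function with known MMT near each location's 78th
percentile):

```bash
python analysis/01_simulate.py     # writes scratch/data + the true AFs
python analysis/02_first_stage.py  # 20 quasi-Poisson DLNM fits, reduced
python analysis/03_pool.py         # REML meta-regression, Wald, Q/I2, BLUPs
python analysis/04_attribution.py  # MMTs, AFs by component, Monte Carlo eCIs
python analysis/05_figures.py      # per-location RR curves (CSV + plots)
```

Output of the run above (seed 1):

```
true pooled AF: total 14.60%, cold 12.13%, heat 2.48%
reduced 20 fits; mean dispersion 1.298 (generative overdispersion is 1.3)
Cochran Q = 80.1 on 70 df (p = 0.193); I2 = 12.6%

 country  mmt_percentile  af_total_pct  af_total_low_pct  af_total_high_pct ...
CountryA            79.0         15.18              9.84              19.55
CountryB            79.0         14.59              9.60              19.09
CountryC            78.0         17.09             11.99              22.08
CountryD            77.0         10.89              6.89              14.51
   Total            78.0         14.45             11.87              16.57

estimated total AF 14.45% (11.87 to 16.57) vs true 14.60%
```

Reading: the first stage recovers the generative overdispersion; pooling
leaves modest residual heterogeneity (I² = 12.6%); each country's median MMT
percentile sits near the true 78th; and the estimated total attributable
fraction 14.45% (eCI 11.87–16.57) covers the exact generative truth 14.60%,
with cold dominating heat exactly as the asymmetric true surface dictates.

The same pipeline runs from the shell on any directory of per-location CSVs:

```bash
tempmort simulate --n-locations 20 --years 5 --seed 1 --out-dir data
tempmort run --data-dir data/series --metadata data/metadata.csv \
             --out-dir results/run --n-sim 1000
tempmort report --results-dir results/run
```

## Layout

- `src/tempmort/` — library: `basis`, `first_stage`, `mvmeta`, `attribution`,
  `synthetic`, `pipeline`, `cli`, `reference`
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite (oracle, property, and calibration tests)
- `docs/methods.md` — modelling assumptions, numerical choices, limitations
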