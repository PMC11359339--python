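# Methods

## The modelling problem

First flowering of kiwifruit vines in New Zealand falls in spring
(roughly day-of-year 294–348, October–December). Its timing is driven by
winter chilling and spring heat accumulation, and it differs systematically
between cultivars: 'Zesy002' flowers roughly 17 days before 'Hayward'.
`phenocast` predicts the first-flowering day of year per vine with a
two-stage procedure: a per-vine budbreak curve is fitted and inverted at 5 %
budbreak, and the resulting degree-day covariate enters a linear
flowering-date regression. The hierarchy matters because budbreak is
observable weeks before flowering, so a grower who has watched budbreak can
tighten the flowering forecast considerably.

## Thermal-time metrics

* **GDD** — growing degree days: daily contribution
  `max(0, mean(hourly temps) − 7 °C)`, summed from 1 July (the Southern
  Hemisphere season start). Clipping negative days at zero is the standard
  GDD convention; it is switchable (`clip_negative=False`) since the verbal
  definition "daily mean minus base, summed" does not force it.
* **CU** — chilling units: the count of hours at or below 7 °C from
  1 January. The threshold is inclusive. The pipeline evaluates CU (and GDD
  and daylength) on 1 September, a fixed anchor date chosen so that
  covariates are not mechanically confounded with the outcome date: a vine
  that flowers later would otherwise accumulate a larger heat sum simply by
  flowering later.
* **Daylength** — astronomical daylength from a cosine solar-declination
  model and the sunrise equation with zenith 90.833° (the standard
  refraction-corrected definition). Valid for |latitude| < 66.5°.
* A day with more than 25 % of its 24 hourly readings missing aborts the
  computation with the offending dates listed. Field weather records carry
  no universal missing-data rule; 25 % is this package's choice, strict
  enough that a daily mean is still meaningful.

## Stage 1 — budbreak curves

Per vine-year (≥ 4 surveys required), cumulative broken-bud counts against
GDD are fitted with

1. a binomial GLM (logit link) on the proportion broken, weighted by bud
   count;
2. a Poisson GLM (log link) on the count;
3. an ordinary least-squares quadratic on the count.

The families are compared by AIC (ties: fewer parameters, then binomial);
r² is reported as the squared Pearson correlation between observed and
fitted proportions, a definition that applies uniformly across the
non-Gaussian families. The cumulative counts are serially dependent, so the
GLM likelihoods are working approximations — the same pragmatic treatment a
field analyst applies — and the AIC comparison is used only to rank curve
shapes.

**Inversion.** BB is the smallest GDD ≥ 0 at which the fitted expected
proportion reaches 5 % of the vine's own final observed budbreak ("5 % of
the total budbreak"); an alternative anchored at 5 % of all buds is
available (`of_total_buds=True`). The crossing is bracketed on a dense grid
over [0, 1.5 × max observed GDD] and solved by bisection to 0.01
degree-days; for the possibly non-monotone quadratic the first crossing is
used. A curve that never reaches the level in that range flags the vine and
excludes it. All-zero or fully saturated count series are likewise excluded
with a logged reason.

## Stage 2 — flowering regressions

Covariates are CV (1 = 'Hayward'), BB, DD (GDD on 1 Sep), CU (chill hours
on 1 Sep) and DL (daylength on 1 Sep). BB, DD and CU are carried in
hundreds of units so that all covariates are O(1) and the reference
coefficient set (intercept 312.7, 10.9 per unit BB, …) maps onto days of
year in the observed flowering window.

Nine candidate predictor sets (`CV.DL`, `CV.DD`, `CV.BB`, `CV.CU`,
`CV.BB.DD`, `CV.BB.CU`, `CV.BB.DL`, `CV.DD.DL`, `CV.CU.DL`) are fitted by
OLS with full interactions on the training years and compared by training
AIC. The winner is refined by bidirectional stepwise AIC that respects
marginality (an interaction is never retained or added without its
lower-order margins); ties prefer the smaller model, and the refined model
never has a higher AIC than its start. Stepwise retains a single truly null
term with probability P(χ²₁ > 2) ≈ 0.16 — an inherent property of the AIC
criterion, reflected in the test expectations.

**Prediction intervals.** For a new record,
`SE_pred = sqrt(SE_mean² + σ̂²)` and the 99 % interval is
`ŷ ± 2.576 · SE_pred`, with 2.576 the two-sided standard-normal critical
value (used verbatim rather than a t quantile). Including the residual
variance is what makes the interval a *prediction* interval: when
SE_mean ≪ σ̂ the width approaches 2 × 2.576 × RMSE, which is the regime the
reference interval widths (~21–23 days at RMSE ≈ 4.1) correspond to.
Coverage is the percentage of held-out vines whose observed day falls in
their own interval; on correctly specified synthetic data it is 99 % ± 2 %
at n = 2000. Records whose numeric predictors fall more than one
range-width outside the training range are flagged `extrapolated`.

**Evaluation.** The train/test split is by calendar year (train 2016–2019,
test 2020–2021 in the synthetic study), mirroring the operational question
"predict next season from past seasons". Test cultivars absent from
training are excluded with a warning. K-fold cross-validation (k = 5,
seeded fold assignment by record, so each training fold holds 80 % of the
data) reports per-fold RMSE/R²/MAE with mean and min–max range.

**Positional analysis.** On a single-orchard subset observed over ≥ 2 years
with row and bay labels, every candidate is fitted twice — with and without
row and bay as categorical main effects (treatment coding; categorical
variables do not enter interactions). Unseen test levels are pooled into
the reference level with a warning. Within a single site, constants such as
daylength alias the intercept; these fits therefore drop aliased design
columns as R's `lm` does, while the default fitting path treats rank
deficiency as an error naming the collinear columns.

## Classification baseline

One instance per vine per 3-day date from 1 September to 31 December,
labelled 1 once the vine's first flower is open. Predictors are DD and CU —
by default their value on 1 September, optionally their accumulation from
1 September to the instance date (`predictor_mode='to_date'`) — plus region
and cultivar; orchard is deliberately excluded (incomplete overlap between
train and test). Numeric predictors are scaled and centered with
training-set statistics. Models: logistic regression (unpenalised) and a
seeded 500-tree random forest. With the default anchored predictors the
classifiers cannot localise the flowering date within a season and collapse
to the majority class — the motivating failure for the regression
approach, and the package reproduces it rather than hiding it.

## Descriptive ANOVAs

The analysis unit is the orchard-year-cultivar stratum: per stratum the
mean first-flowering day and the within-stratum range (max − min; strata
with one vine are excluded). Each response is analysed by a region ×
cultivar two-way ANOVA with Type-II sums of squares (equal to Type-I on
balanced layouts). Group means are reported ± SE.

## The synthetic generator

The generator is the package's study design; its defaults are fixed once:

| parameter | default | rationale |
|---|---|---|
| region winter mean (°C) | Kerikeri 10.8, Te Puke 9.0 | mild- vs cold-winter contrast; Te Puke accumulates several hundred more chill hours by 1 Sep |
| seasonal amplitude (°C) | 4.6 / 5.2 | annual mean ≈ 15.4 / 14.2 °C, NZ coastal ranges |
| diurnal amplitude (°C) | 4 | typical coastal day-night swing |
| hourly noise | AR(1), ρ = 0.95, sd 2 °C | persistent synoptic variability |
| year anomaly sd (°C) | 0.6 | whole-season warm/cold years; the source of between-year DD/CU variation |
| budbreak threshold (dd) | Zesy002 200, Hayward 270 | orders budbreak (and, through the flowering model, flowering) ≈ 17 d apart between cultivars |
| per-vine threshold sd (dd) | 25 | vines of a cultivar differ in chilling/vigour; gives BB real predictive content beyond cultivar |
| logistic slope (dd⁻¹) | 0.05 | budbreak transition spread over ~120 dd, several surveys wide |
| buds per vine | 40 | configurable; no public per-vine counts exist for untreated vines |
| flowering coefficients | the reference full-data set (intercept 312.7, …) | flowering truth uses each vine's *true* curve-crossing BB, so stage-1 estimation error propagates into stage 2 exactly as in the field |
| residual sd (d) | 4 | matches the reference model's RMSE ≈ 4.1 |
| survey interval (d) | 3 (3 or 4 allowed) | field survey cadence |

Weather is hourly for 1 Jan–31 Dec: annual sinusoid with its minimum in
mid-July (Southern Hemisphere) + diurnal sinusoid + AR(1) noise; every
stream is spawned from `SeedSequence(seed, spawn_key=...)`, so identical
configs reproduce byte-identical datasets. Buds break independently given
GDD (each bud draws a logistic GDD requirement), the population-level proportion
then follows the logistic curve exactly, and surveys report cumulative
counts on the 3/4-day grid — the same interval censoring as real surveys.
Generated flowering days are rounded to whole days and clipped to the
Sep–Dec window [244, 366]; an optional switch additionally censors the
flowering day to the next survey date.

A second, covariate-level simulator (`simulate_flowering_records`) draws
CV ~ Bernoulli(0.5), BB ~ N(2, 0.5), DD ~ N(3, 1) (hundreds of units) plus
nuisance CU and DL directly, bypassing the weather and budbreak stages;
regression-level properties (coefficient recovery, coverage, candidate
selection) are tested against it at n = 300–2000.

What the generator does **not** emulate: frosts and extreme events,
humidity or rainfall, spatial autocorrelation between rows (row/bay effects
are null by construction), within-vine bud correlation, management
treatments such as hydrogen cyanamide (all vines are "untreated"), and
orchard-level microclimates beyond the region contrast. Passing tests
therefore demonstrate internal correctness and statistical calibration of
the machinery under the assumed generative structure, not forecast accuracy
on real orchards.

## Numerical choices and degenerate inputs

* Curve inversion: grid bracketing (4096 points) + Brent's method, xtol
  0.01 dd; inversion consistency (curve value at the root equals the target
  ± 10⁻³) is tested.
* AIC ties in family selection break toward fewer parameters, then toward
  the binomial family; stepwise ties prefer the smaller model.
* CU accumulates through the requested end date (the pipeline uses 1 Sep),
  so the nominal end-of-year bound of the verbal definition is never
  reached.
* Day of year is 1-based; the modelled phenophases never cross the year
  boundary in the Southern Hemisphere.
* Problem sizes in the shipped study (2 regions × 3 orchards × 6 years × 8
  vines; 500-record replicates for regression properties) keep the full
  suite and drivers fast while leaving all statistical checks
  well-powered.

## Known limitations

* No mixed-effects or variance-structure extensions; vine and orchard
  random effects are approximated by fixed covariates only.
* AIC values are compared across likelihood families in stage 1, a
  heuristic inherited from the field workflow.
* The normal (not t) critical value slightly understates interval width at
  small n; at the study's n the difference is negligible.
* DD and CU are strongly negatively correlated between years (cold years:
  more chill, less heat), so candidates differing only in DD vs CU are
  near-exchangeable and selection between them is data-dependent.
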