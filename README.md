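# phenocast

Hierarchical thermal-time models for predicting kiwifruit flowering dates.

Commercial kiwifruit growers need the date of first flowering weeks in
advance to schedule pollination (beehive placement) and pest- and
disease-control interventions. `phenocast` implements a two-stage
("hierarchical") modelling pipeline for the two main New Zealand cultivars,
*Actinidia* 'Hayward' and 'Zesy002', growing in two contrasting regions
(Kerikeri, mild winters; Te Puke, colder winters):

1. **Budbreak stage.** For each vine-year, cumulative broken-bud counts from
   3–4-day field surveys are regressed on growing-degree-day accumulation
   (GDD, base 7 °C from 1 July) with three curve families — a binomial GLM
   on the proportion broken, a Poisson GLM, and a quadratic least-squares
   fit. The minimum-AIC family (in practice the binomial) is inverted to
   **BB**, the GDD at which the curve reaches 5 % of the vine's total
   budbreak.
2. **Flowering stage.** First-flowering day of year is regressed on the
   cultivar indicator CV (1 = 'Hayward') and thermal covariates: BB, the GDD
   on 1 September (DD), chilling hours ≤ 7 °C from 1 January to 1 September
   (CU), and daylength on 1 September (DL). Nine candidate predictor sets
   are fitted with full interactions, compared by AIC on the training years,
   and the winner is refined by bidirectional stepwise AIC respecting
   marginality. Prediction intervals are

   ŷ ± 2.576 · √(SE_mean² + σ̂²),

   the two-sided 99 % normal interval on a new observation, and models are
   scored by the interval width and the percentage of held-out vines
   flowering inside their own interval, plus k-fold cross-validation.

The reference full-data flowering model has the form

f(CV, BB, DD) = 312.7 + 15.1·CV + 10.9·BB − 3.3·DD − 3.5·CV:BB + 1.0·BB:DD

with BB and DD in hundreds of degree-days
(`phenocast.FULL_DATA_COEFFICIENTS`).

Because orchard phenology surveys of this kind are commercially held, the
package ships a first-class **synthetic-data generator**: hourly weather per
region (annual + diurnal sinusoids, AR(1) noise, per-year temperature
anomalies), logistic per-bud budbreak against GDD, and flowering days drawn
from the linear model above. Every downstream stage is developed and tested
against it, including truth-recovery checks.

Also included: a presence/absence flowering classification baseline
(logistic GLM and random forest) and region × cultivar ANOVAs on flowering
means and ranges.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (seed 11) and write their tables to `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_budbreak.py
python analysis/03_flowering_models.py
```

`01_simulate.py` prints:

```
simulated 288 vine-years across 6 orchards, 6 seasons
  Kerikeri: mean CU on 1 Sep 390 h, mean GDD on 1 Sep 232 dd
  Te Puke: mean CU on 1 Sep 652 h, mean GDD on 1 Sep 166 dd
mean first flowering: Hayward day 341.2, Zesy002 day 324.0 (offset 17.2 d)
```

i.e. the colder region accumulates more winter chill and less spring heat,
and 'Zesy002' flowers about 17 days before 'Hayward'. `02_budbreak.py`
reports that the binomial family wins AIC for 100 % of vines with mean
r² ≈ 0.998 and recovers each vine's true 5 %-budbreak GDD to a median error
of ~7 degree-days. `03_flowering_models.py` then prints the candidate
comparison (excerpt):

```
     model  interval_min  interval_max  coverage_pct     aic   r2
     CV.DD         27.16         27.45         98.96 1184.42 0.74
     CV.BB         23.60         24.58         98.96 1131.21 0.81
  CV.BB.DD         23.19         25.40         98.96 1127.48 0.82
  CV.BB.CU         23.12         25.86         98.96 1126.24 0.82
CV.BB.CU_1         23.12         25.86         98.96 1126.24 0.82

selected model: CV.BB.CU (stepwise-refined)
  99% interval width 23.1-25.9 d, coverage 99.0%, R2 0.82
5-fold CV RMSE 4.58 d (range 4.29-5.33), R2 0.79 (range 0.72-0.83)
```

Candidates containing the budbreak covariate BB clearly dominate (narrower
intervals, lower AIC, higher R²); DD and CU are nearly exchangeable because
cold years have high chill and low heat sums. The same pipeline is available
as a CLI:

```bash
phenocast run --seed 11 --out out/          # full pipeline, all tables
phenocast simulate --seed 1 --out data/     # weather + phenology CSVs
```

## Layout

```
src/phenocast/      library: synthetic, thermal, budbreak, flowering,
                    classify, describe, io, pipeline, cli
analysis/           numbered narrative drivers (01_simulate ... 06_descriptive)
tests/              pytest suite, including end-to-end scientific checks
scripts/            acceptance.py
docs/methods.md     modelling assumptions, parameter choices, limitations
results/            small output tables written by the analysis drivers
```
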