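"""End-to-end pipeline: ingest -> thermal time -> budbreak -> flowering.

Each stage is a plain function over DataFrames so the CLI and the analysis
scripts stay thin; :func:`run_pipeline` composes them on a synthetic dataset
and writes all output tables plus a run log.
"""

from __future__ import annotations

import datetime as dt
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import budbreak, classify, describe, flowering, synthetic, thermal
from .config import PipelineConfig

_SCALE = 100.0  # BB/DD/CU are carried in hundreds of units in the records


def stage_thermal(weather_by_region_year: dict[tuple[str, int], pd.DataFrame],
                  config: PipelineConfig) -> tuple[dict, pd.DataFrame]:
    """Thermal summaries per region-year and the 1-September metric table."""
    summaries: dict[tuple[str, int], pd.DataFrame] = {}
    metric_rows = []
    for (region, year), weather in weather_by_region_year.items():
        season_start = dt.date.fromisoformat(f"{year}-{config.season_start}")
        summary = thermal.thermal_summary(
            weather, season_start=season_start, year_start=dt.date(year, 1, 1),
            through=dt.date(year, 12, 31), base_temp=config.base_temp_c,
            cu_threshold=config.cu_threshold_c)
        summaries[(region, year)] = summary
        at = summary.set_index("date").loc[dt.date.fromisoformat(f"{year}-{config.metric_date}")]
        metric_rows.append({"region": region, "year": year,
                            "dd_sep": float(at["gdd_cum"]), "cu_sep": float(at["cu_cum"]),
                            "dl_sep": float(at["daylength"])})
    return summaries, pd.DataFrame(metric_rows)


def stage_records(budbreak_fits: pd.DataFrame, flowering_table: pd.DataFrame,
                  metrics: pd.DataFrame) -> pd.DataFrame:
    """Merge stage-1 BB estimates with flowering days and weather metrics."""
    # drop generator-truth columns that would collide with the metric names
    rec = flowering_table.drop(columns=["true_bb", "dd_sep"], errors="ignore")
    rec = rec.merge(budbreak_fits[["vine_id", "gdd_at_5pct"]], on="vine_id")
    rec = rec.merge(metrics, on=["region", "year"])
    rec["CV"] = (rec["cultivar"] == "Hayward").astype(float)
    rec["BB"] = rec["gdd_at_5pct"] / _SCALE
    rec["DD"] = rec["dd_sep"] / _SCALE
    rec["CU"] = rec["cu_sep"] / _SCALE
    rec["DL"] = rec["dl_sep"]
    rec["flower_doy"] = rec["first_flower_doy"].astype(float)
    cols = ["vine_id", "cultivar", "CV", "region", "orchard", "year",
            "BB", "DD", "CU", "DL", "flower_doy"]
    for c in ("row", "bay"):
        if c in rec.columns:
            cols.append(c)
    return rec[cols]


@dataclass
class PipelineReport:
    """All tables one pipeline run produces."""

    records: pd.DataFrame
    budbreak_fits: pd.DataFrame
    metrics: pd.DataFrame
    candidate_table: pd.DataFrame
    best_label: str
    prediction_table: pd.DataFrame
    cv_results: dict
    positional_table: pd.DataFrame | None
    classification_table: pd.DataFrame
    classification_metrics: pd.DataFrame
    anova_mean: describe.AnovaResult
    anova_range: describe.AnovaResult
    strata: pd.DataFrame


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None,
                 rf_trees: int = 500) -> PipelineReport:
    """Run the full synthetic study and (optionally) write its tables."""
    dataset = synthetic.simulate_dataset(config.synthetic)
    summaries, metrics = stage_thermal(dataset.weather, config)

    fits = budbreak.fit_panel(dataset.surveys)
    records = stage_records(fits, dataset.flowering, metrics)

    split = flowering.evaluate_year_split(
        records, config.train_years, config.test_years,
        candidates=config.candidates, level=config.interval_level)
    refined = split.fits[f"{split.best_label}_1"]
    cv = flowering.kfold_cv(records, refined.terms, k=config.k, seed=config.seed)

    positional = None
    with_pos = records.dropna(subset=["row", "bay"]) if "row" in records.columns else pd.DataFrame()
    if not with_pos.empty:
        orchard = sorted(with_pos["orchard"].unique())[0]
        sub = with_pos[with_pos["orchard"] == orchard]
        if sub["year"].nunique() >= 2:
            positional = flowering.positional_analysis(
                sub, config.train_years, config.test_years,
                candidates=config.candidates, level=config.interval_level)

    instances = classify.build_instances(
        dataset.flowering, summaries,
        interval_days=config.synthetic.survey_interval_days,
        metric_date=config.metric_date)
    train_i = instances[instances["year"].isin(config.train_years)]
    test_i = instances[instances["year"].isin(config.test_years)]
    clf = classify.fit_classifiers(train_i, seed=config.seed, n_trees=rf_trees)
    confusion = classify.confusion_table(clf, test_i)
    clf_metrics = classify.classification_metrics(clf, test_i)

    strata = describe.stratum_table(dataset.flowering)
    anova_mean = describe.anova_two_way(strata, "mean_doy")
    anova_range = describe.anova_two_way(strata, "range_days")

    report = PipelineReport(
        records=records, budbreak_fits=fits, metrics=metrics,
        candidate_table=split.table, best_label=split.best_label,
        prediction_table=split.predictions[f"{split.best_label}_1"],
        cv_results=cv, positional_table=positional,
        classification_table=confusion, classification_metrics=clf_metrics,
        anova_mean=anova_mean, anova_range=anova_range, strata=strata,
    )
    if outdir is not None:
        write_report(report, config, Path(outdir))
    return report


def write_report(report: PipelineReport, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.records.to_csv(outdir / "flowering_records.csv", index=False)
    report.budbreak_fits.to_csv(outdir / "budbreak_fits.csv", index=False)
    report.metrics.to_csv(outdir / "thermal_metrics.csv", index=False)
    report.candidate_table.to_csv(outdir / "candidate_models.csv", index=False)
    report.prediction_table.to_csv(outdir / "predictions_best_model.csv", index=False)
    if report.positional_table is not None:
        report.positional_table.to_csv(outdir / "positional_models.csv", index=False)
    report.classification_table.to_csv(outdir / "classification_confusion.csv", index=False)
    report.classification_metrics.to_csv(outdir / "classification_metrics.csv", index=False)
    report.anova_mean.table.to_csv(outdir / "anova_mean_doy.csv", index=False)
    report.anova_range.table.to_csv(outdir / "anova_range_days.csv", index=False)
    report.strata.to_csv(outdir / "flowering_strata.csv", index=False)
    log = {
        "seed": config.seed,
        "synthetic_seed": config.synthetic.seed,
        "best_model": report.best_label,
        "cv": {k: v for k, v in report.cv_results.items() if not k.endswith("_folds")},
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
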