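"""Presence/absence flowering classification (logistic GLM vs random forest).

Each instance is one vine on one survey date between 1 September and
31 December, labelled 1 once the vine's first flower has opened. Predictors
are thermal covariates (degree days and chilling units, either their value
on 1 September or their accumulation from 1 September to the instance date)
plus region and cultivar; orchard is deliberately not a predictor. Numeric
predictors are scaled and centered with training-set statistics.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .errors import DegenerateFitError, SchemaError

logger = logging.getLogger(__name__)

NUMERIC_PREDICTORS = ("DD", "CU")
LABEL_PREDICTORS = ("region", "cultivar")


def build_instances(flowering: pd.DataFrame,
                    thermal_by_region_year: dict[tuple[str, int], pd.DataFrame],
                    interval_days: int = 3, predictor_mode: str = "metric_date",
                    metric_date: str = "09-01") -> pd.DataFrame:
    """One labelled instance per vine per date on a 1 Sep - 31 Dec grid.

    ``predictor_mode='metric_date'`` uses DD/CU on 1 September (the default);
    ``'to_date'`` uses their accumulation from 1 September to the instance
    date. Units: hundreds of degree-days / chill hours.
    """
    if predictor_mode not in ("metric_date", "to_date"):
        raise SchemaError(f"unknown predictor_mode {predictor_mode!r}")
    rows = []
    for (region, year), summary in thermal_by_region_year.items():
        by_date = summary.set_index("date")
        anchor = dt.date.fromisoformat(f"{year}-{metric_date}")
        start, end = dt.date(year, 9, 1), dt.date(year, 12, 31)
        grid = []
        d = start
        while d <= end:
            grid.append(d)
            d += dt.timedelta(days=interval_days)
        sub = flowering[(flowering["region"] == region) & (flowering["year"] == year)]
        for _, vine in sub.iterrows():
            for d in grid:
                if predictor_mode == "metric_date":
                    dd = by_date.loc[anchor, "gdd_cum"]
                    cu = by_date.loc[anchor, "cu_cum"]
                else:
                    row = by_date.loc[min(d, by_date.index.max())]
                    dd = row["gdd_cum"] - by_date.loc[anchor, "gdd_cum"]
                    cu = row["cu_cum"] - by_date.loc[anchor, "cu_cum"]
                rows.append({
                    "vine_id": vine["vine_id"], "region": region,
                    "cultivar": vine["cultivar"], "year": year, "date": d,
                    "DD": dd / 100.0, "CU": cu / 100.0,
                    "flowering": int(d.timetuple().tm_yday >= vine["first_flower_doy"]),
                })
    return pd.DataFrame(rows)


@dataclass
class FittedClassifiers:
    """Logistic regression + random forest sharing one training scaler."""

    logistic: LogisticRegression
    forest: RandomForestClassifier
    numeric: tuple[str, ...]
    labels: tuple[str, ...]
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    label_levels: dict[str, list[str]] = field(default_factory=dict)

    def design(self, instances: pd.DataFrame) -> np.ndarray:
        """Scaled/centered numeric block + treatment-coded label dummies."""
        cols = []
        for var in self.numeric:
            x = instances[var].to_numpy(float)
            cols.append((x - self.means[var]) / self.sds[var])
        for var in self.labels:
            values = instances[var].astype(str)
            for level in self.label_levels[var][1:]:
                cols.append((values == level).to_numpy(float))
        return np.column_stack(cols)

    def predict(self, instances: pd.DataFrame) -> pd.DataFrame:
        X = self.design(instances)
        return pd.DataFrame({
            "logistic": self.logistic.predict(X).astype(int),
            "random_forest": self.forest.predict(X).astype(int),
        }, index=instances.index)


def fit_classifiers(train: pd.DataFrame, seed: int = 0, n_trees: int = 500,
                    numeric: tuple[str, ...] = NUMERIC_PREDICTORS,
                    labels: tuple[str, ...] = LABEL_PREDICTORS) -> FittedClassifiers:
    """Fit the logistic and random-forest classifiers on training instances."""
    y = train["flowering"].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise DegenerateFitError("training data contain a single class")
    numeric = tuple(v for v in numeric if v in train.columns)
    labels = tuple(v for v in labels if v in train.columns and train[v].nunique() > 1)
    fitted = FittedClassifiers(
        logistic=LogisticRegression(penalty=None, max_iter=2000),
        forest=RandomForestClassifier(n_estimators=n_trees, random_state=seed),
        numeric=numeric, labels=labels,
    )
    for var in numeric:
        x = train[var].to_numpy(float)
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 1.0
        fitted.means[var] = float(np.mean(x))
        fitted.sds[var] = sd if sd > 0 else 1.0
    for var in labels:
        fitted.label_levels[var] = sorted(train[var].astype(str).unique())
    X = fitted.design(train)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separable data never fully converge
        fitted.logistic.fit(X, y)
    fitted.forest.fit(X, y)
    return fitted


def confusion_table(fitted: FittedClassifiers, test: pd.DataFrame) -> pd.DataFrame:
    """Per region x cultivar percentage in each (prediction, flowering) cell.

    The four cells of each stratum sum to 100%. Strata with no test
    instances are omitted with a warning.
    """
    preds = fitted.predict(test)
    rows = []
    for (region, cultivar), grp in test.groupby(["region", "cultivar"], sort=True):
        if grp.empty:
            logger.warning("empty stratum %s/%s omitted", region, cultivar)
            continue
        n = len(grp)
        for p in (0, 1):
            for f in (0, 1):
                row = {"region": region, "cultivar": cultivar,
                       "prediction": p, "flowering": f, "n": n}
                for model in ("logistic", "random_forest"):
                    hits = ((preds.loc[grp.index, model] == p)
                            & (grp["flowering"] == f)).sum()
                    row[model] = 100.0 * hits / n
                rows.append(row)
    return pd.DataFrame(rows)


def classification_metrics(fitted: FittedClassifiers, test: pd.DataFrame) -> pd.DataFrame:
    """Overall accuracy, sensitivity and specificity per model and stratum."""
    preds = fitted.predict(test)
    rows = []
    groups = [(("all", "all"), test)] + list(test.groupby(["region", "cultivar"], sort=True))
    for (region, cultivar), grp in groups:
        y = grp["flowering"].to_numpy(int)
        for model in ("logistic", "random_forest"):
            p = preds.loc[grp.index, model].to_numpy(int)
            pos, neg = y == 1, y == 0
            rows.append({
                "region": region, "cultivar": cultivar, "model": model,
                "accuracy_pct": 100.0 * float(np.mean(p == y)),
                "sensitivity_pct": 100.0 * float(np.mean(p[pos] == 1)) if pos.any() else np.nan,
                "specificity_pct": 100.0 * float(np.mean(p[neg] == 0)) if neg.any() else np.nan,
            })
    return pd.DataFrame(rows)
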