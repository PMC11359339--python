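"""Descriptive summaries: two-way ANOVAs on flowering-time means and ranges.

The analysis unit is the orchard-year-cultivar stratum: per stratum the mean
first-flowering day and the within-stratum range (max - min) are computed,
then each is analysed with a region x cultivar two-way ANOVA (Type-II sums
of squares).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import SchemaError

logger = logging.getLogger(__name__)

STRATUM_KEYS = ("region", "cultivar", "orchard", "year")


def flowering_range(values) -> float:
    """Range (max - min) of first-flowering days, in days."""
    v = np.asarray(values, dtype=float)
    return float(v.max() - v.min())


def stratum_table(flowering: pd.DataFrame, keys=STRATUM_KEYS,
                  response: str = "first_flower_doy") -> pd.DataFrame:
    """Per-stratum mean and range of the response.

    Strata with fewer than two vines are excluded with a warning (their
    range is undefined).
    """
    missing = [k for k in (*keys, response) if k not in flowering.columns]
    if missing:
        raise SchemaError(f"flowering table missing columns: {missing}")
    rows = []
    for key, grp in flowering.groupby(list(keys), sort=True):
        if len(grp) < 2:
            logger.warning("stratum %s has a single vine; excluded", key)
            continue
        v = grp[response].to_numpy(float)
        rows.append({**dict(zip(keys, key)), "n_vines": len(grp),
                     "mean_doy": float(v.mean()), "range_days": flowering_range(v)})
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    """F table plus group means for a two-way ANOVA."""

    table: pd.DataFrame       # term, F, df_num, df_den, p
    group_means: pd.DataFrame  # factor, level, mean, se, n
    residual_df: int


def anova_two_way(strata: pd.DataFrame, response: str,
                  factors: tuple[str, str] = ("region", "cultivar")) -> AnovaResult:
    """Region x cultivar ANOVA with Type-II sums of squares.

    ``strata`` holds one row per analysis unit (e.g. the stratum means from
    :func:`stratum_table`). Every cell of the factor grid must be occupied.
    """
    a, b = factors
    counts = strata.groupby([a, b]).size()
    for la in strata[a].unique():
        for lb in strata[b].unique():
            if (la, lb) not in counts.index:
                raise SchemaError(f"empty cell in the {a} x {b} grid: ({la!r}, {lb!r})")
    if len(strata) < 4:
        raise SchemaError("need >= 2 groups with >= 2 observations for a two-way ANOVA")

    df = strata.rename(columns={response: "_y", a: "_a", b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    aov = anova_lm(model, typ=2)
    resid_df = int(aov.loc["Residual", "df"])
    term_names = {"C(_a)": a, "C(_b)": b, "C(_a):C(_b)": f"{a}:{b}"}
    rows = [{"term": term_names[t], "F": float(aov.loc[t, "F"]),
             "df_num": int(aov.loc[t, "df"]), "df_den": resid_df,
             "p": float(aov.loc[t, "PR(>F)"])} for t in term_names]

    means = []
    for factor in factors:
        for level, grp in strata.groupby(factor, sort=True):
            v = grp[response].to_numpy(float)
            means.append({"factor": factor, "level": level, "n": len(v),
                          "mean": float(v.mean()),
                          "se": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan})
    return AnovaResult(table=pd.DataFrame(rows), group_means=pd.DataFrame(means),
                       residual_df=resid_df)
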