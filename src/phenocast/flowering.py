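"""Stage 2: flowering-date regressions, intervals, and model selection.

The response is the first-flowering day of year; candidate predictor sets
combine the cultivar indicator CV (1 = 'Hayward') with thermal covariates:
BB (GDD at predicted 5% budbreak), DD (GDD on 1 September), CU (chill hours
on 1 September) and DL (daylength on 1 September). Candidates are first
fitted with full interactions, the AIC-best candidate is refined by
bidirectional stepwise AIC (respecting marginality), and 99% prediction
intervals are formed as point +/- 2.576 x prediction SE, where the SE
includes both the mean-estimation and the residual components.

Design matrices are built from explicit term sets (tuples of variable
names); row and bay enter as categorical main effects only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, SchemaError
from .linmodel import interval_critical_value

logger = logging.getLogger(__name__)

Term = tuple[str, ...]

NUMERIC_VARS = ("CV", "BB", "DD", "CU", "DL")
CANDIDATE_LABELS = ("CV.DL", "CV.DD", "CV.BB", "CV.CU", "CV.BB.DD",
                    "CV.BB.CU", "CV.BB.DL", "CV.DD.DL", "CV.CU.DL")
RESPONSE = "flower_doy"


def parse_candidate(label: str) -> tuple[str, ...]:
    """'CV.BB.DD' -> ('CV', 'BB', 'DD'); validates the variable set."""
    variables = tuple(label.split("."))
    unknown = set(variables) - set(NUMERIC_VARS)
    if unknown:
        raise ConfigError(f"candidate {label!r} uses unknown predictors {sorted(unknown)}")
    return variables


def full_interaction_terms(variables: tuple[str, ...]) -> tuple[Term, ...]:
    """All main effects and interactions (every non-empty subset)."""
    order = {v: i for i, v in enumerate(variables)}
    terms = []
    for k in range(1, len(variables) + 1):
        for combo in itertools.combinations(variables, k):
            terms.append(tuple(sorted(combo, key=order.get)))
    return tuple(terms)


def term_label(term: Term) -> str:
    return ":".join(term)


def _is_categorical(records: pd.DataFrame, var: str) -> bool:
    return var in records.columns and not pd.api.types.is_numeric_dtype(records[var])


@dataclass
class DesignInfo:
    """Everything needed to rebuild the design on new data."""

    terms: tuple[Term, ...]
    columns: list[str]
    categories: dict[str, list[str]] = field(default_factory=dict)
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)


def build_design(records: pd.DataFrame, terms: tuple[Term, ...],
                 info: DesignInfo | None = None) -> tuple[pd.DataFrame, DesignInfo]:
    """Design matrix (with intercept) for a term set.

    Numeric interaction terms are elementwise products; categorical
    variables (row, bay) contribute treatment-coded dummy blocks and may
    appear only as main effects. Passing a training ``DesignInfo`` rebuilds
    the design on new data with the training categories and ranges; unseen
    categorical levels are pooled into the reference level with a warning.
    """
    needed = sorted({v for t in terms for v in t})
    missing = [v for v in needed if v not in records.columns]
    if missing:
        raise SchemaError(f"records missing predictor columns: {missing}")

    fitting = info is None
    categories = {} if fitting else info.categories
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(records))}
    for term in terms:
        cats = [v for v in term if _is_categorical(records, v)]
        if cats and len(term) > 1:
            raise SchemaError(
                f"categorical variables only enter as main effects, got {term_label(term)}")
        if cats:
            var = term[0]
            values = records[var].astype(str)
            if fitting:
                levels = sorted(values.unique())
                categories[var] = levels
            else:
                levels = categories[var]
                unseen = set(values) - set(levels)
                if unseen:
                    logger.warning("unseen %s levels %s pooled into reference level",
                                   var, sorted(unseen))
            for level in levels[1:]:  # first level is the reference
                cols[f"{var}[{level}]"] = (values == level).to_numpy(float)
        else:
            x = np.ones(len(records))
            for v in term:
                x = x * records[v].to_numpy(float)
            cols[term_label(term)] = x
    X = pd.DataFrame(cols, index=records.index)

    if fitting:
        ranges = {v: (float(records[v].min()), float(records[v].max()))
                  for v in needed if not _is_categorical(records, v)}
        info = DesignInfo(terms=tuple(terms), columns=list(X.columns),
                          categories=categories, ranges=ranges)
    else:
        X = X.reindex(columns=info.columns, fill_value=0.0)
    return X, info


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Columns linearly dependent on the columns before them (left to right)."""
    arr = X.to_numpy(float)
    kept: list[int] = []
    dropped: list[str] = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if kept:
            beta, *_ = np.linalg.lstsq(arr[:, kept], col, rcond=None)
            resid = col - arr[:, kept] @ beta
            if np.linalg.norm(resid) <= 1e-8 * max(np.linalg.norm(col), 1.0):
                dropped.append(X.columns[j])
                continue
        elif np.linalg.norm(col) == 0:
            dropped.append(X.columns[j])
            continue
        kept.append(j)
    return dropped


@dataclass
class FloweringFit:
    """An OLS flowering-date model with its training diagnostics."""

    terms: tuple[Term, ...]
    info: DesignInfo
    results: object  # statsmodels RegressionResults
    aic: float
    r_squared: float
    rmse: float
    mae: float
    n: int
    on_collinear: str = "error"

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.info.columns, np.asarray(self.results.params)))


def fit_ols(records: pd.DataFrame, terms: tuple[Term, ...],
            response: str = RESPONSE, on_collinear: str = "error") -> FloweringFit:
    """Ordinary least squares of the response on the term-set design.

    A rank-deficient design raises by default, naming the collinear
    columns; ``on_collinear='drop'`` instead discards the aliased columns
    (as R's ``lm`` does), which single-site subsets need because site
    constants like daylength alias the intercept there.
    """
    X, info = build_design(records, terms)
    collinear = _collinear_columns(X)
    if collinear:
        if on_collinear != "drop":
            raise SchemaError(f"design is rank deficient; collinear terms: {collinear}")
        logger.warning("dropping aliased design columns: %s", collinear)
        X = X.drop(columns=collinear)
        info.columns = list(X.columns)
    y = records[response].to_numpy(float)
    if len(y) <= X.shape[1]:
        raise SchemaError(f"n={len(y)} too small for {X.shape[1]} terms")
    res = sm.OLS(y, X).fit()
    resid = y - res.fittedvalues
    return FloweringFit(terms=tuple(terms), info=info, results=res,
                        aic=float(res.aic), r_squared=float(res.rsquared),
                        rmse=float(np.sqrt(np.mean(resid ** 2))),
                        mae=float(np.mean(np.abs(resid))), n=len(y),
                        on_collinear=on_collinear)


# ---------------------------------------------------------------------------
# stepwise refinement

def _droppable(current: set[Term]) -> list[Term]:
    """Terms with no strict superset in the model (marginality-safe drops)."""
    return [t for t in current
            if not any(set(t) < set(u) for u in current if u != t)]


def _addable(current: set[Term], scope: set[Term]) -> list[Term]:
    """Absent scope terms whose lower-order margins are all present."""
    out = []
    for t in scope - current:
        subs = [s for s in scope if set(s) < set(t)]
        if all(s in current for s in subs):
            out.append(t)
    return out


def stepwise_refine(records: pd.DataFrame, fit: FloweringFit,
                    response: str = RESPONSE) -> FloweringFit:
    """Bidirectional stepwise AIC within the starting model's scope.

    Drops or adds one term at a time (never violating marginality), accepts
    the move with the lowest AIC while it improves, and prefers the smaller
    model on ties. The result never has a higher AIC than the input.
    """
    scope = set(fit.terms)
    current = set(fit.terms)
    cache: dict[frozenset, FloweringFit] = {frozenset(current): fit}

    def fitted(terms: set[Term]) -> FloweringFit:
        key = frozenset(terms)
        if key not in cache:
            ordered = tuple(t for t in fit.terms if t in terms)
            cache[key] = fit_ols(records, ordered, response=response,
                                 on_collinear=fit.on_collinear)
        return cache[key]

    best = fitted(current)
    while True:
        moves: list[tuple[float, int, set[Term]]] = []
        for t in _droppable(current):
            trial = current - {t}
            if trial:
                moves.append((fitted(trial).aic, len(trial), trial))
        for t in _addable(current, scope):
            trial = current | {t}
            moves.append((fitted(trial).aic, len(trial), trial))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1]))
        aic, _, trial = moves[0]
        if aic < best.aic - 1e-10 or (abs(aic - best.aic) <= 1e-10
                                      and len(trial) < len(current)):
            current = trial
            best = fitted(current)
        else:
            break
    return best


# ---------------------------------------------------------------------------
# prediction intervals

def predict_with_interval(fit: FloweringFit, new_records: pd.DataFrame,
                          level: float = 0.99, response: str = RESPONSE) -> pd.DataFrame:
    """Point predictions with normal-theory prediction intervals.

    The prediction SE combines the SE of the fitted mean with the residual
    standard deviation, ``sqrt(se_mean^2 + sigma2)``; the interval is
    point +/- z(level) x SE with z(0.99) = 2.576. Records whose numeric
    predictors fall far outside the training range (beyond one range-width
    past either end, i.e. a 3x-range window) are flagged ``extrapolated``.
    """
    X, _ = build_design(new_records, fit.terms, info=fit.info)
    pred = fit.results.get_prediction(X.to_numpy(float))
    point = np.asarray(pred.predicted_mean)
    se_mean = np.asarray(pred.se_mean)
    sigma2 = float(fit.results.mse_resid)
    se_pred = np.sqrt(se_mean ** 2 + sigma2)
    z = interval_critical_value(level)

    extrapolated = np.zeros(len(new_records), dtype=bool)
    for var, (lo, hi) in fit.info.ranges.items():
        if var not in new_records.columns:
            continue
        width = hi - lo
        x = new_records[var].to_numpy(float)
        extrapolated |= (x < lo - width) | (x > hi + width)

    table = pd.DataFrame({
        "predicted_doy": point,
        "lower": point - z * se_pred,
        "upper": point + z * se_pred,
        "interval_width": 2 * z * se_pred,
        "extrapolated": extrapolated,
    }, index=new_records.index)
    if "vine_id" in new_records.columns:
        table.insert(0, "vine_id", new_records["vine_id"])
    if response in new_records.columns:
        observed = new_records[response].to_numpy(float)
        table["observed_doy"] = observed
        table["inside"] = (observed >= table["lower"]) & (observed <= table["upper"])
    return table


def coverage_percent(prediction_table: pd.DataFrame) -> float:
    """Percentage of observed flowering days inside their own interval."""
    return 100.0 * float(prediction_table["inside"].mean())


# ---------------------------------------------------------------------------
# candidate comparison on a year-based train/test split

@dataclass
class YearSplitResult:
    table: pd.DataFrame
    best_label: str
    fits: dict[str, FloweringFit]
    predictions: dict[str, pd.DataFrame]


def evaluate_year_split(records: pd.DataFrame, train_years, test_years,
                        candidates=CANDIDATE_LABELS, level: float = 0.99,
                        extra_terms: tuple[Term, ...] = (),
                        response: str = RESPONSE,
                        on_collinear: str = "error") -> YearSplitResult:
    """Fit every candidate on the training years, score on the test years.

    For each candidate the table reports training AIC and R^2, the min and
    max 99% interval width over the test set, and the percentage of observed
    flowering inside the intervals. The AIC-best candidate is then refined
    by stepwise AIC and appended with a ``_1`` suffix.
    ``extra_terms`` (e.g. categorical row/bay main effects) are appended to
    every candidate's term set.
    """
    train = records[records["year"].isin(train_years)]
    test = records[records["year"].isin(test_years)]
    if train.empty or test.empty:
        raise ConfigError("both train and test year splits must be non-empty")
    if "cultivar" in records.columns:
        unseen = set(test["cultivar"]) - set(train["cultivar"])
        if unseen:
            logger.warning("test cultivars %s absent from training; excluded", sorted(unseen))
            test = test[~test["cultivar"].isin(unseen)]

    rows, fits, preds = [], {}, {}

    def score(label: str, fit: FloweringFit) -> None:
        pt = predict_with_interval(fit, test, level=level, response=response)
        fits[label], preds[label] = fit, pt
        rows.append({"model": label,
                     "interval_min": float(pt["interval_width"].min()),
                     "interval_max": float(pt["interval_width"].max()),
                     "coverage_pct": coverage_percent(pt),
                     "aic": fit.aic, "r2": fit.r_squared})

    for label in candidates:
        terms = full_interaction_terms(parse_candidate(label)) + tuple(extra_terms)
        score(label, fit_ols(train, terms, response=response, on_collinear=on_collinear))

    best_label = min(candidates, key=lambda c: fits[c].aic)
    refined = stepwise_refine(train, fits[best_label], response=response)
    score(f"{best_label}_1", refined)
    return YearSplitResult(table=pd.DataFrame(rows), best_label=best_label,
                           fits=fits, predictions=preds)


# ---------------------------------------------------------------------------
# k-fold cross-validation

def kfold_cv(records: pd.DataFrame, terms: tuple[Term, ...], k: int = 5,
             seed: int = 0, response: str = RESPONSE) -> dict:
    """Seeded k-fold CV: per-fold RMSE / R^2 / MAE, with mean and range.

    With k=5 each training fold holds 80% of the records.
    """
    n = len(records)
    if k > n:
        raise ConfigError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    rmse, r2, mae, train_sizes = [], [], [], []
    for fold in folds:
        mask = np.zeros(n, dtype=bool)
        mask[fold] = True
        train, test = records.iloc[~mask], records.iloc[mask]
        fit = fit_ols(train, terms, response=response)
        X, _ = build_design(test, fit.terms, info=fit.info)
        pred = fit.results.predict(X.to_numpy(float))
        y = test[response].to_numpy(float)
        resid = y - pred
        rmse.append(float(np.sqrt(np.mean(resid ** 2))))
        mae.append(float(np.mean(np.abs(resid))))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2.append(1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else np.nan)
        train_sizes.append(len(train))
    out = {"train_sizes": train_sizes, "fold_sizes": [len(f) for f in folds]}
    for name, vals in (("rmse", rmse), ("r2", r2), ("mae", mae)):
        out[f"{name}_mean"] = float(np.mean(vals))
        out[f"{name}_min"] = float(np.min(vals))
        out[f"{name}_max"] = float(np.max(vals))
        out[f"{name}_folds"] = vals
    return out


# ---------------------------------------------------------------------------
# within-orchard positional analysis

def positional_analysis(records: pd.DataFrame, train_years, test_years,
                        candidates=CANDIDATE_LABELS, level: float = 0.99,
                        response: str = RESPONSE) -> pd.DataFrame:
    """Compare candidates with and without row/bay position predictors.

    Requires records from a single orchard observed with row and bay labels
    over at least two years. Each candidate is fitted twice on the training
    years — once with row and bay as categorical main effects, once without
    — and scored on the test years; the AIC-best candidate of each version
    is stepwise-refined and appended with a ``_1`` suffix.
    """
    for col in ("row", "bay"):
        if col not in records.columns:
            raise SchemaError(f"positional analysis requires a {col!r} column")
    if records["orchard"].nunique() > 1:
        raise SchemaError("positional analysis expects records from a single orchard")
    if records["year"].nunique() < 2:
        raise SchemaError("positional analysis requires >= 2 years of records")

    frames = []
    for mode, extra in (("included", (("row",), ("bay",))), ("excluded", ())):
        res = evaluate_year_split(records, train_years, test_years,
                                  candidates=candidates, level=level,
                                  extra_terms=extra, response=response,
                                  on_collinear="drop")
        t = res.table.copy()
        t.insert(1, "row_bay", mode)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
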