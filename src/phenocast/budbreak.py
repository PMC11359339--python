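"""Stage 1: per-vine budbreak curves and the GDD at 5% budbreak.

For each vine-year, cumulative broken-bud counts against growing-degree-day
accumulation are fitted with three model families — a binomial GLM on the
proportion broken, a Poisson GLM on the count, and a quadratic least-squares
fit on the count. The minimum-AIC family is selected and the fitted curve is
inverted to the GDD at which it reaches 5% of the vine's final observed
budbreak ("BB"), the covariate the stage-2 flowering regression consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq

from .errors import DegenerateFitError, ExtrapolationError, SchemaError

logger = logging.getLogger(__name__)

FAMILIES = ("binomial", "poisson", "polynomial")
#: number of estimated parameters per family (used only for AIC tie-breaks)
_N_PARAMS = {"binomial": 2, "poisson": 2, "polynomial": 3}

#: how far beyond the last observed GDD the inversion may extrapolate
EXTRAPOLATION_FACTOR = 1.5
#: bisection tolerance on the inverted GDD, in degree-days
INVERSION_TOL = 0.01


@dataclass
class FamilyFit:
    """One fitted curve family for one vine."""

    family: str
    coefficients: np.ndarray
    aic: float
    r_squared: float
    total_buds: int

    def predict_proportion(self, gdd) -> np.ndarray:
        """Expected proportion of buds broken at the given GDD values."""
        g = np.asarray(gdd, dtype=float)
        b = self.coefficients
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-(b[0] + b[1] * g)))
        if self.family == "poisson":
            return np.exp(b[0] + b[1] * g) / self.total_buds
        if self.family == "polynomial":
            return (b[0] + b[1] * g + b[2] * g ** 2) / self.total_buds
        raise ValueError(f"unknown family {self.family!r}")


@dataclass
class BudbreakFit:
    """Selected best family plus the inverted 5% budbreak GDD."""

    vine_id: str
    family: str
    coefficients: np.ndarray
    aic: float
    r_squared: float
    gdd_at_5pct: float
    extrapolated: bool
    fit: FamilyFit


def _validate_survey(survey: pd.DataFrame) -> pd.DataFrame:
    required = {"gdd_cum", "broken_buds", "total_buds"}
    missing = required - set(survey.columns)
    if missing:
        raise SchemaError(f"budbreak survey missing columns: {sorted(missing)}")
    s = survey.sort_values("gdd_cum").reset_index(drop=True)
    if len(s) < 4:
        raise SchemaError(f"need >= 4 observations per vine, got {len(s)}")
    broken = s["broken_buds"].to_numpy()
    if np.any(np.diff(broken) < 0):
        raise SchemaError("broken_buds must be non-decreasing over survey dates")
    if np.any(broken > s["total_buds"].to_numpy()):
        raise SchemaError("broken_buds exceeds total_buds")
    return s


def fit_budbreak_curves(survey: pd.DataFrame) -> dict[str, FamilyFit]:
    """Fit the three candidate families to one vine's survey.

    Raises :class:`DegenerateFitError` when the counts carry no curve
    information (all zero or saturated from the first survey on).
    """
    s = _validate_survey(survey)
    gdd = s["gdd_cum"].to_numpy(float)
    broken = s["broken_buds"].to_numpy(float)
    total = int(s["total_buds"].iloc[0])
    if broken.max() == 0:
        raise DegenerateFitError("no budbreak observed; curve undefined")
    if broken.min() == broken.max():
        raise DegenerateFitError("budbreak saturated before the first survey")

    X = sm.add_constant(gdd)
    fits: dict[str, FamilyFit] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            binom = sm.GLM(np.column_stack([broken, total - broken]), X,
                           family=sm.families.Binomial()).fit()
            fits["binomial"] = FamilyFit("binomial", np.asarray(binom.params),
                                         float(binom.aic), np.nan, total)
        except Exception as exc:  # perfect separation etc.
            logger.warning("binomial fit failed: %s", exc)
        try:
            pois = sm.GLM(broken, X, family=sm.families.Poisson()).fit()
            fits["poisson"] = FamilyFit("poisson", np.asarray(pois.params),
                                        float(pois.aic), np.nan, total)
        except Exception as exc:
            logger.warning("poisson fit failed: %s", exc)
        Xq = sm.add_constant(np.column_stack([gdd, gdd ** 2]))
        poly = sm.OLS(broken, Xq).fit()
        fits["polynomial"] = FamilyFit("polynomial", np.asarray(poly.params),
                                       float(poly.aic), np.nan, total)

    observed_prop = broken / total
    for fit in fits.values():
        fitted = fit.predict_proportion(gdd)
        if np.std(fitted) == 0 or np.std(observed_prop) == 0:
            fit.r_squared = 0.0
        else:
            fit.r_squared = float(np.corrcoef(observed_prop, fitted)[0, 1] ** 2)
    return fits


def select_best_family(fits: dict[str, FamilyFit]) -> FamilyFit:
    """Minimum-AIC family; ties go to fewer parameters, then to binomial."""
    if len(fits) < 2:
        raise DegenerateFitError("need >= 2 successful family fits to select")
    order = {fam: i for i, fam in enumerate(FAMILIES)}  # binomial first
    return min(fits.values(), key=lambda f: (f.aic, _N_PARAMS[f.family], order[f.family]))


def invert_at_5pct(fit: FamilyFit, survey: pd.DataFrame,
                   of_total_buds: bool = False) -> tuple[float, bool]:
    """Smallest GDD >= 0 where the fitted curve reaches the 5% level.

    The level is 5% of the vine's final observed budbreak proportion
    (or of the full bud count with ``of_total_buds=True``). Root-finding is
    bracketed bisection to 0.01 degree-days; for the (possibly non-monotone)
    polynomial family the first crossing on a dense grid is used. Returns
    ``(gdd, extrapolated)`` where ``extrapolated`` flags a crossing beyond
    the observed GDD range.
    """
    s = _validate_survey(survey)
    gdd_max = float(s["gdd_cum"].max())
    final_prop = 1.0 if of_total_buds else float(
        s["broken_buds"].iloc[-1] / s["total_buds"].iloc[-1])
    target = 0.05 * final_prop

    hi = EXTRAPOLATION_FACTOR * gdd_max
    grid = np.linspace(0.0, hi, 4096)
    vals = fit.predict_proportion(grid) - target
    if vals[0] >= 0:
        return 0.0, False
    crossings = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
    if len(crossings) == 0:
        raise ExtrapolationError(
            f"fitted {fit.family} curve never reaches {target:.4f} within GDD {hi:.0f}")
    i = crossings[0]
    root = brentq(lambda g: float(fit.predict_proportion(g) - target),
                  grid[i], grid[i + 1], xtol=INVERSION_TOL)
    return float(root), bool(root > gdd_max)


def fit_vine(survey: pd.DataFrame, vine_id: str | None = None,
             of_total_buds: bool = False) -> BudbreakFit:
    """Full stage-1 pipeline for one vine: fit, select, invert."""
    if vine_id is None:
        vine_id = str(survey["vine_id"].iloc[0]) if "vine_id" in survey.columns else "vine"
    fits = fit_budbreak_curves(survey)
    best = select_best_family(fits)
    gdd5, extrapolated = invert_at_5pct(best, survey, of_total_buds=of_total_buds)
    return BudbreakFit(vine_id=vine_id, family=best.family, coefficients=best.coefficients,
                       aic=best.aic, r_squared=best.r_squared, gdd_at_5pct=gdd5,
                       extrapolated=extrapolated, fit=best)


def fit_panel(surveys: pd.DataFrame, of_total_buds: bool = False) -> pd.DataFrame:
    """Fit every vine in a survey table; degenerate vines are excluded.

    Returns one row per successfully fitted vine with columns
    ``vine_id, family, aic, r2, gdd_at_5pct, flag`` plus any per-vine
    metadata (orchard, region, cultivar, year, row, bay) carried through.
    """
    meta_cols = [c for c in ("orchard", "region", "cultivar", "year", "row", "bay")
                 if c in surveys.columns]
    rows = []
    for vine_id, grp in surveys.groupby("vine_id", sort=True):
        try:
            fit = fit_vine(grp, vine_id=str(vine_id), of_total_buds=of_total_buds)
        except (DegenerateFitError, ExtrapolationError, SchemaError) as exc:
            logger.warning("vine %s excluded: %s", vine_id, exc)
            continue
        row = {"vine_id": vine_id, "family": fit.family, "aic": fit.aic,
               "r2": fit.r_squared, "gdd_at_5pct": fit.gdd_at_5pct,
               "flag": "extrapolated" if fit.extrapolated else ""}
        for c in meta_cols:
            row[c] = grp[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
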