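"""Synthetic weather and vine-phenology generator.

The generator emulates the statistical structure the downstream analysis
assumes: two New Zealand growing regions with different winter chilling,
two kiwifruit cultivars ('Hayward' and 'Zesy002') whose buds break as a
logistic function of growing-degree-day accumulation, and a first-flowering
day generated from a linear model in cultivar and thermal-time covariates.
Surveys report cumulative broken-bud counts on a 3- or 4-day grid, the same
interval-censored design as a field survey.

Everything is deterministic given the config seed: per-stream RNGs are
spawned from ``numpy.random.SeedSequence`` keyed by region/year/vine index.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import CULTIVARS, REGIONS, SyntheticConfig
from .errors import ConfigError, GenerationError
from .linmodel import evaluate_coefficients
from . import thermal

#: mid-July day of year, the Southern Hemisphere annual temperature minimum
_WINTER_TROUGH_DOY = 196.5
#: local hour of the diurnal temperature maximum
_DIURNAL_PEAK_HOUR = 14.0

_LOGIT_5PCT = float(np.log(0.05 / 0.95))


def _weather_rng(config: SyntheticConfig, region: str, year: int) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(0, REGIONS.index(region), year))
    return np.random.default_rng(ss)


def weather_mean_function(config: SyntheticConfig, region: str,
                          timestamps: pd.DatetimeIndex) -> np.ndarray:
    """Deterministic two-sinusoid temperature mean (annual + diurnal)."""
    rp = config.region_params[region]
    doy_frac = (timestamps.dayofyear - 1 + timestamps.hour / 24.0).to_numpy(float)
    annual = rp.winter_mean_c + rp.amplitude_c * (
        1.0 - np.cos(2 * np.pi * (doy_frac - _WINTER_TROUGH_DOY) / 365.25))
    diurnal = -config.diurnal_amplitude_c * np.cos(
        2 * np.pi * (timestamps.hour.to_numpy(float) - _DIURNAL_PEAK_HOUR) / 24.0)
    return annual + diurnal


def simulate_weather(config: SyntheticConfig, region: str, year: int,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Hourly temperature series for one region-year (1 Jan - 31 Dec).

    Temperature = annual sinusoid (minimum in July) + diurnal sinusoid +
    AR(1) hourly noise with stationary sd ``config.noise_sd_c`` and
    autocorrelation ``config.ar_rho``.
    """
    if region not in config.region_params:
        raise ConfigError(f"unknown region {region!r}; known: {sorted(config.region_params)}")
    if rng is None:
        rng = _weather_rng(config, region, year)
    ts = pd.date_range(f"{year}-01-01", f"{year}-12-31 23:00", freq="h")
    mean = weather_mean_function(config, region, ts)
    if config.year_anomaly_sd_c > 0:
        mean = mean + rng.normal(0.0, config.year_anomaly_sd_c)
    if config.noise_sd_c > 0:
        burn = 500
        z = rng.standard_normal(len(ts) + burn)
        innov_sd = config.noise_sd_c * np.sqrt(1.0 - config.ar_rho ** 2)
        noise = lfilter([innov_sd], [1.0, -config.ar_rho], z)[burn:]
    else:
        noise = np.zeros(len(ts))
    return pd.DataFrame({
        "station": f"{region} AWS",
        "latitude": config.region_params[region].latitude,
        "timestamp": ts,
        "temp_c": mean + noise,
    })


def true_gdd_at_5pct(config: SyntheticConfig, cultivar: str) -> float:
    """GDD at which the cultivar's logistic budbreak curve crosses 5%."""
    cp = config.cultivar_params[cultivar]
    return cp.gdd_threshold + _LOGIT_5PCT / cp.logistic_slope


def _survey_dates(config: SyntheticConfig, year: int) -> list[dt.date]:
    start = dt.date.fromisoformat(f"{year}-{config.survey_start}")
    end = dt.date.fromisoformat(f"{year}-{config.survey_end}")
    step = dt.timedelta(days=config.survey_interval_days)
    dates, d = [], start
    while d <= end:
        dates.append(d)
        d += step
    return dates


def simulate_vine_phenology(config: SyntheticConfig, weather: pd.DataFrame, cultivar: str,
                            rng: np.random.Generator, vine_id: str = "vine",
                            ) -> tuple[pd.DataFrame, int, dict]:
    """One vine's budbreak survey and first-flowering day.

    Each of ``buds_per_vine`` buds draws an independent GDD requirement from
    Logistic(gdd_threshold, 1/logistic_slope); a survey on date *d* reports
    how many requirements fall at or below the GDD accumulated by *d*. The
    vine's true BB is the GDD at the 5% point of that logistic curve, and its
    flowering day is the configured linear model evaluated at (CV, BB, DD on
    1 Sep) plus Gaussian residual, rounded to the nearest day.

    Returns ``(survey table, flowering day-of-year, truth dict)``.
    """
    if cultivar not in config.cultivar_params:
        raise ConfigError(f"unknown cultivar {cultivar!r}")
    cp = config.cultivar_params[cultivar]
    year = int(pd.to_datetime(weather["timestamp"].iloc[0]).year)
    season_start = dt.date(year, 7, 1)
    season_end = dt.date(year, 12, 31)
    gdd = thermal.accumulate_gdd(weather, season_start, season_end)
    gdd_by_date = dict(zip(gdd["date"], gdd["gdd_cum"]))
    season_max = float(gdd["gdd_cum"].iloc[-1])

    dates = _survey_dates(config, year)
    gdd_at_survey = np.array([gdd_by_date[d] for d in dates])
    threshold = cp.gdd_threshold
    if config.vine_threshold_sd > 0:
        threshold = threshold + rng.normal(0.0, config.vine_threshold_sd)
    if not 0.0 <= threshold <= season_max:
        raise GenerationError(
            f"vine {vine_id}: budbreak threshold {threshold:.1f} dd outside the "
            f"season GDD range [0, {season_max:.1f}]")
    bud_req = rng.logistic(loc=threshold, scale=1.0 / cp.logistic_slope,
                           size=config.buds_per_vine)
    broken = (bud_req[None, :] <= gdd_at_survey[:, None]).sum(axis=1)

    bb = threshold + _LOGIT_5PCT / cp.logistic_slope
    dd = float(gdd_by_date[dt.date(year, 9, 1)])
    cv = 1.0 if cultivar == "Hayward" else 0.0
    lp = evaluate_coefficients(config.flowering_coefficients,
                               {"CV": cv, "BB": bb / 100.0, "DD": dd / 100.0})
    resid = rng.normal(0.0, config.residual_sd) if config.residual_sd > 0 else 0.0
    flower_doy = int(np.clip(round(lp + resid), 244, 366))
    if config.censor_flowering_to_survey:
        flower_date = dt.date(year, 1, 1) + dt.timedelta(days=flower_doy - 1)
        later = [d for d in dates if d >= flower_date]
        if later:
            flower_doy = later[0].timetuple().tm_yday

    survey = pd.DataFrame({
        "vine_id": vine_id,
        "survey_date": dates,
        "gdd_cum": gdd_at_survey,
        "broken_buds": broken,
        "total_buds": config.buds_per_vine,
    })
    truth = {"true_bb": bb, "dd_sep": dd, "cv": cv, "linear_predictor": lp}
    return survey, flower_doy, truth


@dataclass
class SyntheticDataset:
    """Bundle of everything one simulated study produces."""

    weather: dict[tuple[str, int], pd.DataFrame]
    surveys: pd.DataFrame
    flowering: pd.DataFrame
    truth: SyntheticConfig = field(repr=False)


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Simulate the full multi-region, multi-year, multi-vine study."""
    weather: dict[tuple[str, int], pd.DataFrame] = {}
    for region in REGIONS:
        for year in config.years:
            weather[(region, year)] = simulate_weather(config, region, year)

    surveys, flowering = [], []
    vine_counter = 0
    for region in REGIONS:
        prefix = "KK" if region == "Kerikeri" else "TP"
        for o in range(1, config.n_orchards_per_region + 1):
            orchard = f"{prefix}-O{o}"
            for year in config.years:
                for v in range(config.n_vines_per_orchard):
                    cultivar = CULTIVARS[v % len(CULTIVARS)]
                    vine_id = f"{orchard}-{year}-v{v + 1}"
                    rng = np.random.default_rng(
                        np.random.SeedSequence(config.seed, spawn_key=(1, vine_counter)))
                    vine_counter += 1
                    survey, doy, truth = simulate_vine_phenology(
                        config, weather[(region, year)], cultivar, rng, vine_id=vine_id)
                    meta = {
                        "orchard": orchard, "region": region, "cultivar": cultivar,
                        # paired rows with alternating bays keep row/bay
                        # balanced across cultivars (no aliasing with CV)
                        "year": year, "row": f"R{v // 2 % 4 + 1}",
                        "bay": f"B{(v + v // 2) % 2 + 1}",
                    }
                    survey = survey.assign(**meta)
                    surveys.append(survey)
                    flowering.append({"vine_id": vine_id, **meta,
                                      "first_flower_doy": doy,
                                      "true_bb": truth["true_bb"],
                                      "dd_sep": truth["dd_sep"]})
    survey_cols = ["orchard", "region", "cultivar", "year", "row", "bay", "vine_id",
                   "survey_date", "gdd_cum", "broken_buds", "total_buds"]
    return SyntheticDataset(
        weather=weather,
        surveys=pd.concat(surveys, ignore_index=True)[survey_cols],
        flowering=pd.DataFrame(flowering),
        truth=config,
    )


def simulate_flowering_records(n: int, coefficients: dict[str, float],
                               rng: np.random.Generator, residual_sd: float = 4.0,
                               years: tuple[int, ...] = tuple(range(2016, 2022)),
                               ) -> pd.DataFrame:
    """Covariate-level flowering records drawn directly from a linear model.

    Bypasses the weather/budbreak stages: CV ~ Bernoulli(0.5),
    BB ~ N(2, 0.5), DD ~ N(3, 1) (hundreds of degree-days), plus nuisance
    covariates CU ~ N(8, 1.5) (hundreds of chill hours) and DL ~ N(11.7, 0.3)
    hours that do not enter the response. Used for regression-level
    property checks where the full phenology pipeline is not needed.
    """
    cv = rng.integers(0, 2, size=n).astype(float)
    df = pd.DataFrame({
        "CV": cv,
        "cultivar": np.where(cv == 1, "Hayward", "Zesy002"),
        "BB": rng.normal(2.0, 0.5, size=n),
        "DD": rng.normal(3.0, 1.0, size=n),
        "CU": rng.normal(8.0, 1.5, size=n),
        "DL": rng.normal(11.7, 0.3, size=n),
        "year": rng.choice(years, size=n),
    })
    lp = evaluate_coefficients(coefficients, df)
    df["flower_doy"] = lp + rng.normal(0.0, residual_sd, size=n)
    df["vine_id"] = [f"v{i}" for i in range(n)]
    return df
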