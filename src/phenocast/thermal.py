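"""Thermal-time metrics from hourly temperature series.

Three quantities drive the phenology models:

* growing degree days (GDD): daily mean temperature minus a 7 degC base,
  negative contributions clipped at zero, summed from the season start
  (1 July in the Southern Hemisphere);
* chilling units (CU): the count of hours at or below 7 degC from 1 January;
* astronomical daylength from latitude and date.

Hourly weather is a pandas DataFrame with columns ``station``, ``latitude``,
``timestamp`` (naive local time) and ``temp_c``.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .errors import DataQualityError, DomainError, SchemaError

WEATHER_COLUMNS = ("station", "latitude", "timestamp", "temp_c")

#: fraction of a day's 24 hourly readings that may be missing before the
#: day is rejected
MAX_MISSING_FRACTION = 0.25


def _check_weather(weather: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("timestamp", "temp_c") if c not in weather.columns]
    if missing:
        raise SchemaError(f"weather table missing columns: {missing}")
    ts = pd.to_datetime(weather["timestamp"])
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise SchemaError("weather timestamps must be strictly increasing")
    t = weather["temp_c"].to_numpy(float)
    if np.any(t < -30) or np.any(t > 50):
        raise SchemaError("temperatures outside the [-30, 50] degC sanity bound")
    out = weather.copy()
    out["timestamp"] = ts
    return out


def _daily_frame(weather: pd.DataFrame, start: dt.date, through: dt.date) -> pd.DataFrame:
    w = _check_weather(weather)
    day = w["timestamp"].dt.date
    mask = (day >= start) & (day <= through)
    w = w.loc[mask]
    if w.empty:
        raise DataQualityError(f"no weather records in [{start}, {through}]")
    grouped = w.groupby(w["timestamp"].dt.date)["temp_c"]
    counts = grouped.count()
    bad = counts[counts < 24 * (1 - MAX_MISSING_FRACTION)]
    # also flag days absent entirely from the record
    all_days = pd.date_range(start, through, freq="D").date
    absent = sorted(set(all_days) - set(counts.index))
    if len(bad) or absent:
        dates = sorted(list(bad.index) + absent)
        raise DataQualityError(f"days with > {MAX_MISSING_FRACTION:.0%} missing hours: {dates}")
    return pd.DataFrame({"date": counts.index, "mean_temp": grouped.mean().to_numpy(),
                         "n_hours": counts.to_numpy()})


def accumulate_gdd(weather: pd.DataFrame, season_start: dt.date, through: dt.date,
                   base_temp: float = 7.0, clip_negative: bool = True) -> pd.DataFrame:
    """Accumulated growing degree days per calendar day.

    The daily contribution is ``mean(hourly temps) - base_temp``, clipped at
    zero by default (standard GDD convention), summed from ``season_start``.
    Returns one row per day with columns ``date`` and ``gdd_cum``.
    """
    daily = _daily_frame(weather, season_start, through)
    contrib = daily["mean_temp"].to_numpy() - base_temp
    if clip_negative:
        contrib = np.clip(contrib, 0.0, None)
    return pd.DataFrame({"date": daily["date"], "gdd_cum": np.cumsum(contrib)})


def accumulate_cu(weather: pd.DataFrame, year_start: dt.date, through: dt.date,
                  threshold: float = 7.0) -> pd.DataFrame:
    """Accumulated chilling units (hours at or below ``threshold``) per day.

    The threshold is inclusive. Returns columns ``date`` and ``cu_cum``.
    """
    w = _check_weather(weather)
    day = w["timestamp"].dt.date
    w = w.loc[(day >= year_start) & (day <= through)]
    if w.empty:
        raise DataQualityError(f"no weather records in [{year_start}, {through}]")
    # reuse the missing-hours gate
    _daily_frame(weather, year_start, through)
    chill = (w["temp_c"].to_numpy(float) <= threshold).astype(int)
    per_day = pd.Series(chill).groupby(w["timestamp"].dt.date.to_numpy()).sum()
    return pd.DataFrame({"date": per_day.index, "cu_cum": per_day.cumsum().to_numpy()})


_ZENITH_DEG = 90.833  # refraction-corrected sunrise/sunset zenith


def daylength(latitude: float, date: dt.date) -> float:
    """Astronomical daylength in hours at ``latitude`` on ``date``.

    Uses a cosine solar-declination model and the standard sunrise equation
    with zenith 90.833 deg. Valid only outside the polar circles.
    """
    if abs(latitude) >= 66.5:
        raise DomainError(f"latitude {latitude} is polar; daylength undefined year-round")
    doy = date.timetuple().tm_yday
    decl = np.deg2rad(-23.44 * np.cos(2 * np.pi * (doy + 10) / 365.25))
    lat = np.deg2rad(latitude)
    cos_h = (np.cos(np.deg2rad(_ZENITH_DEG)) - np.sin(lat) * np.sin(decl)) / (
        np.cos(lat) * np.cos(decl))
    cos_h = float(np.clip(cos_h, -1.0, 1.0))
    return 2 * np.degrees(np.arccos(cos_h)) / 15.0


def thermal_summary(weather: pd.DataFrame, season_start: dt.date, year_start: dt.date,
                    through: dt.date, base_temp: float = 7.0,
                    cu_threshold: float = 7.0) -> pd.DataFrame:
    """Per-day GDD, CU and daylength over [season_start, through].

    CU accumulates from ``year_start`` (1 January); the returned table is
    restricted to the GDD season so the two align row-for-row.
    """
    gdd = accumulate_gdd(weather, season_start, through, base_temp=base_temp)
    cu = accumulate_cu(weather, year_start, through, threshold=cu_threshold)
    lat = float(weather["latitude"].iloc[0]) if "latitude" in weather.columns else np.nan
    out = gdd.merge(cu, on="date", how="left")
    out["daylength"] = [daylength(lat, d) if np.isfinite(lat) else np.nan for d in out["date"]]
    return out
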