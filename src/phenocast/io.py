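"""Schema-validated CSV readers and writers for every pipeline table."""

from __future__ import annotations

import pandas as pd

from .errors import SchemaError

WEATHER_COLUMNS = ["station", "latitude", "timestamp", "temp_c"]
PHENOLOGY_COLUMNS = ["orchard", "region", "cultivar", "year", "row", "bay", "vine_id",
                     "survey_date", "broken_buds", "total_buds", "first_flower_doy"]
THERMAL_COLUMNS = ["date", "gdd_cum", "cu_cum", "daylength"]
RECORD_COLUMNS = ["vine_id", "cultivar", "CV", "region", "orchard", "year",
                  "BB", "DD", "CU", "DL", "flower_doy"]


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; found {list(df.columns)}")


def write_weather_csv(weather: pd.DataFrame, path) -> None:
    _require(weather, WEATHER_COLUMNS, path)
    weather.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["timestamp", "temp_c"], path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_phenology_csv(phenology: pd.DataFrame, path) -> None:
    _require(phenology, PHENOLOGY_COLUMNS, path)
    phenology.to_csv(path, index=False)


def read_phenology_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, PHENOLOGY_COLUMNS, path)
    df["survey_date"] = pd.to_datetime(df["survey_date"]).dt.date
    bad = df.index[(df["broken_buds"] < 0) | (df["broken_buds"] > df["total_buds"])]
    if len(bad):
        raise SchemaError(f"{path}: broken_buds outside [0, total_buds] at rows {list(bad[:5])}")
    return df


def write_thermal_csv(summary: pd.DataFrame, path) -> None:
    _require(summary, THERMAL_COLUMNS, path)
    summary.to_csv(path, index=False)


def read_thermal_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, THERMAL_COLUMNS, path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_records_csv(records: pd.DataFrame, path) -> None:
    _require(records, RECORD_COLUMNS, path)
    records.to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, RECORD_COLUMNS, path)
    if not df["CV"].isin([0, 1]).all():
        raise SchemaError(f"{path}: CV must be 0/1")
    return df
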