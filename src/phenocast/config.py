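"""Configuration objects for the synthetic generator and the pipeline.

All tunables of the study design live here: the two growing regions and
their winter temperature regimes, the two cultivars and their thermal
budbreak requirements, the flowering-date linear model used to generate
synthetic truth, and the survey design (interval, bud counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .errors import ConfigError

REGIONS = ("Kerikeri", "Te Puke")
CULTIVARS = ("Hayward", "Zesy002")

#: Final full-dataset flowering model: first-flower day of year as a linear
#: function of cultivar indicator CV (1 = 'Hayward'), degree-day accumulation
#: at predicted 5% budbreak BB, and degree-day accumulation on 1 September DD
#: (BB and DD in hundreds of degree-days).
FULL_DATA_COEFFICIENTS: dict[str, float] = {
    "Intercept": 312.7,
    "CV": 15.1,
    "BB": 10.9,
    "DD": -3.3,
    "CV:BB": -3.5,
    "BB:DD": 1.0,
}

#: Final model refitted on the single-orchard (row/bay) data subset.
SINGLE_ORCHARD_COEFFICIENTS: dict[str, float] = {
    "Intercept": 471.2,
    "CV": 32.1,
    "BB": 0.09,
    "DD": -0.61,
    "CV:BB": -0.06,
}


@dataclass(frozen=True)
class RegionParams:
    """Climate of one growing region.

    winter_mean_c is the mean temperature at the annual minimum (mid July);
    amplitude_c is half the seasonal swing, so the annual mean sits at
    winter_mean_c + amplitude_c.
    """

    winter_mean_c: float
    amplitude_c: float
    latitude: float


@dataclass(frozen=True)
class CultivarParams:
    """Thermal budbreak requirement of one cultivar.

    Each bud's budbreak GDD requirement is Logistic(gdd_threshold,
    1/logistic_slope), so the population budbreak proportion follows
    expit(logistic_slope * (GDD - gdd_threshold)).
    """

    gdd_threshold: float
    logistic_slope: float


def _default_regions() -> dict[str, RegionParams]:
    return {
        "Kerikeri": RegionParams(winter_mean_c=10.8, amplitude_c=4.6, latitude=-35.22),
        "Te Puke": RegionParams(winter_mean_c=9.0, amplitude_c=5.2, latitude=-37.78),
    }


def _default_cultivars() -> dict[str, CultivarParams]:
    return {
        "Zesy002": CultivarParams(gdd_threshold=200.0, logistic_slope=0.05),
        "Hayward": CultivarParams(gdd_threshold=270.0, logistic_slope=0.05),
    }


@dataclass
class SyntheticConfig:
    """Full parameterisation of the synthetic study."""

    seed: int = 0
    n_years: int = 6
    start_year: int = 2016
    n_orchards_per_region: int = 3
    n_vines_per_orchard: int = 8
    region_params: dict[str, RegionParams] = field(default_factory=_default_regions)
    cultivar_params: dict[str, CultivarParams] = field(default_factory=_default_cultivars)
    flowering_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(FULL_DATA_COEFFICIENTS)
    )
    residual_sd: float = 4.0
    survey_interval_days: int = 3
    buds_per_vine: int = 40
    #: sd of the per-vine shift in the budbreak GDD threshold (degree-days);
    #: makes BB vary between vines of a cultivar, as in real orchards
    vine_threshold_sd: float = 25.0
    # weather process
    diurnal_amplitude_c: float = 4.0
    noise_sd_c: float = 2.0
    ar_rho: float = 0.95
    #: sd of the whole-year mean temperature anomaly (degC); the source of
    #: realistic between-season variation in GDD and CU
    year_anomaly_sd_c: float = 0.6
    # survey design
    survey_start: str = "08-01"
    survey_end: str = "11-30"
    censor_flowering_to_survey: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.residual_sd < 0:
            raise ConfigError("residual_sd must be >= 0")
        if self.survey_interval_days not in (3, 4):
            raise ConfigError("survey_interval_days must be 3 or 4")
        for name in ("n_years", "n_orchards_per_region", "n_vines_per_orchard", "buds_per_vine"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if set(self.region_params) != set(REGIONS):
            raise ConfigError(f"region_params must have exactly the regions {REGIONS}")
        if set(self.cultivar_params) != set(CULTIVARS):
            raise ConfigError(f"cultivar_params must have exactly the cultivars {CULTIVARS}")
        if "Intercept" not in self.flowering_coefficients:
            raise ConfigError("flowering_coefficients must contain an 'Intercept'")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start_year, self.start_year + self.n_years))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "region_params" in d:
            d["region_params"] = {k: RegionParams(**v) if isinstance(v, Mapping) else v
                                  for k, v in d["region_params"].items()}
        if "cultivar_params" in d:
            d["cultivar_params"] = {k: CultivarParams(**v) if isinstance(v, Mapping) else v
                                    for k, v in d["cultivar_params"].items()}
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (synthetic ingest + analysis stages)."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    base_temp_c: float = 7.0
    cu_threshold_c: float = 7.0
    season_start: str = "07-01"
    metric_date: str = "09-01"
    train_years: tuple[int, ...] = (2016, 2017, 2018, 2019)
    test_years: tuple[int, ...] = (2020, 2021)
    candidates: tuple[str, ...] = (
        "CV.DL", "CV.DD", "CV.BB", "CV.CU",
        "CV.BB.DD", "CV.BB.CU", "CV.BB.DL", "CV.DD.DL", "CV.CU.DL",
    )
    k: int = 5
    interval_level: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        train, test = set(self.train_years), set(self.test_years)
        if train & test:
            raise ConfigError(f"train/test years overlap: {sorted(train & test)}")
        if not 0 < self.interval_level < 1:
            raise ConfigError("interval_level must be in (0, 1)")
        if self.k < 2:
            raise ConfigError("k must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw:
            raw["synthetic"] = SyntheticConfig.from_dict(raw["synthetic"])
        for key in ("train_years", "test_years", "candidates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
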