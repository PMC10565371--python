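"""Configuration objects shared across the pipeline.

All thresholds used by the filtering steps (minimum age, minimum encounters
per monthly window, minimum sightings per individual per window) live here as
defaults and are never hard-coded elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration object fails validation."""


@dataclass
class ReactionNormCovariance:
    """2x2 covariance of individual random intercepts and slopes."""

    v_intercept: float = 0.2
    v_slope: float = 0.05
    cov: float = 0.0

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [[self.v_intercept, self.cov], [self.cov, self.v_slope]], dtype=float
        )

    def validate(self) -> None:
        if self.v_intercept < 0 or self.v_slope < 0:
            raise ConfigurationError("variances must be non-negative")
        if self.cov**2 > self.v_intercept * self.v_slope + 1e-12:
            raise ConfigurationError(
                "rn_covariance is not positive semi-definite: "
                f"|cov|={abs(self.cov):.4g} exceeds sqrt(V_int*V_slope)="
                f"{np.sqrt(self.v_intercept * self.v_slope):.4g}"
            )


@dataclass
class FixedEffects:
    """Population-level effects on the latent gregariousness scale."""

    intercept: float = 0.0
    env: float = 0.0
    sex: float = 0.0
    sex_env: float = 0.0


@dataclass
class SimulationConfig:
    n_individuals: int = 129
    n_years: int = 32
    first_year: int = 1990
    months_active: Sequence[int] = (5, 6, 7, 8, 9)
    surveys_per_year: tuple[int, int] = (9, 35)
    mean_surveys_per_year: int | None = 22
    detection_prob: float = 0.84
    presence_prob: float = 0.5
    sex_ratio: float = 0.5
    unknown_sex_frac: float = 0.1
    unknown_birth_year_frac: float = 0.5
    birth_year_range: tuple[int, int] = (1960, 1995)
    env_model: str = "ar1_index"
    env_ar1_rho: float = 0.3
    env_count_mean: float = 200.0
    env_count_dispersion: float = 5.0
    env_seasonal_amplitude: float = 1.0
    fixed_effects: FixedEffects = field(default_factory=FixedEffects)
    rn_covariance: ReactionNormCovariance = field(
        default_factory=ReactionNormCovariance
    )
    n_communities: int = 3
    community_affinity_ratio: float = 3.0
    group_concentration: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if self.n_years < 1:
            raise ConfigurationError("n_years must be >= 1")
        if not (0.0 < self.detection_prob <= 1.0):
            raise ConfigurationError("detection_prob must be in (0, 1]")
        if not (0.0 < self.presence_prob <= 1.0):
            raise ConfigurationError("presence_prob must be in (0, 1]")
        lo, hi = self.surveys_per_year
        if lo < 1 or hi < lo:
            raise ConfigurationError("surveys_per_year bounds must satisfy 1 <= lo <= hi")
        if self.env_model not in ("ar1_index", "seasonal_count"):
            raise ConfigurationError(f"unknown env_model: {self.env_model!r}")
        if not all(1 <= m <= 12 for m in self.months_active):
            raise ConfigurationError("months_active must be month indices 1..12")
        if self.n_communities < 1:
            raise ConfigurationError("n_communities must be >= 1")
        if self.community_affinity_ratio <= 0:
            raise ConfigurationError("community_affinity_ratio must be > 0")
        self.rn_covariance.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["months_active"] = list(self.months_active)
        d["surveys_per_year"] = list(self.surveys_per_year)
        d["birth_year_range"] = list(self.birth_year_range)
        return d


@dataclass
class Thresholds:
    """Filtering thresholds; defaults follow the study protocol."""

    min_age: int = 3
    min_encounters_per_month: int = 10
    min_sightings: int = 5


@dataclass
class ModelSpec:
    trait: str = "strength"  # strength | clustering | closeness
    covariate: str = "climate_index"  # climate_index | resource_count
    timescale: str = "year"  # year | month
    transform: str = "log"  # log | logit | identity
    random_structure: str = "full"  # full | zero_corr | intercept_only
    include_month_effect: bool | None = None  # default: timescale == "month"
    include_year_ar1: bool = True
    clustering_variant: str = "barrat"  # barrat | onnela
    sd_convention: str = "population"  # population | sample

    TRAITS = ("strength", "clustering", "closeness")
    COVARIATES = ("climate_index", "resource_count")
    TIMESCALES = ("year", "month")

    def __post_init__(self) -> None:
        if self.include_month_effect is None:
            self.include_month_effect = self.timescale == "month"

    def validate(self) -> None:
        if self.trait not in self.TRAITS:
            raise ConfigurationError(f"unknown trait: {self.trait!r}")
        if self.covariate not in self.COVARIATES:
            raise ConfigurationError(f"unknown covariate: {self.covariate!r}")
        if self.timescale not in self.TIMESCALES:
            raise ConfigurationError(f"unknown timescale: {self.timescale!r}")
        if self.transform not in ("log", "logit", "identity"):
            raise ConfigurationError(f"unknown transform: {self.transform!r}")
        if self.random_structure not in ("full", "zero_corr", "intercept_only"):
            raise ConfigurationError(
                f"unknown random_structure: {self.random_structure!r}"
            )
        if self.include_month_effect and self.timescale != "month":
            raise ConfigurationError("month random effect only at monthly timescale")

    @staticmethod
    def default_transform(trait: str) -> str:
        # strength/closeness are right-skewed positives; clustering lives in (0,1)
        return "logit" if trait == "clustering" else "log"


def load_yaml_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "fixed_effects" in d and isinstance(d["fixed_effects"], dict):
        d["fixed_effects"] = FixedEffects(**d["fixed_effects"])
    if "rn_covariance" in d and isinstance(d["rn_covariance"], dict):
        d["rn_covariance"] = ReactionNormCovariance(**d["rn_covariance"])
    for key in ("surveys_per_year", "birth_year_range"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg
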