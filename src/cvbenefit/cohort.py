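"""Synthetic survey-weighted cohort generation and inclusion filtering.

The generator emulates the structure of a national blood-sample survey of
Chinese adults: ages 40-80, a slight female majority, LDL-C restricted to
[1.8, 4.9) mmol/L, and survey weights that scale the sample to hundreds of
millions of persons.  All distributional defaults are documented synthetic
stand-ins exposed through :class:`GeneratorConfig`; they are not estimates
of any real survey's covariate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

__all__ = [
    "CohortRecord",
    "GeneratorConfig",
    "COHORT_COLUMNS",
    "EXCLUSION_ORDER",
    "generate_cohort",
    "apply_inclusion_filters",
    "rescale_weights",
]

#: Column order of the cohort table (and its CSV serialization).
COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "smoker",
    "sbp",
    "tc",
    "ldl",
    "hdl",
    "weight",
    "cvd_history",
    "diabetes",
    "statin_use",
]

#: Fixed order in which exclusion reasons are checked; a record removed for
#: several reasons is tallied under the first matching one.
EXCLUSION_ORDER = [
    "age_outside_40_80",
    "cvd_history",
    "diabetes",
    "ldl_below_1.8",
    "ldl_at_or_above_4.9",
    "statin_use",
]

AGE_MIN, AGE_MAX = 40.0, 80.0
LDL_MIN, LDL_MAX = 1.8, 4.9


@dataclass(frozen=True)
class CohortRecord:
    """One person's covariates, exclusion flags, and survey weight."""

    id: str
    age: float
    sex: str  # "M" or "F"
    smoker: bool
    sbp: float
    tc: float
    ldl: float
    hdl: float
    weight: float
    cvd_history: bool = False
    diabetes: bool = False
    statin_use: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if self.ldl <= 0:
            raise ValueError(f"ldl must be positive, got {self.ldl}")
        if self.tc < self.ldl:
            raise ValueError(f"tc ({self.tc}) must be >= ldl ({self.ldl})")
        if not 60 < self.sbp < 260:
            raise ValueError(f"sbp must lie in (60, 260), got {self.sbp}")
        if not 18 < self.age < 110:
            raise ValueError(f"age must lie in (18, 110), got {self.age}")


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic cohort generator.

    Defaults target a cohort with mean age ~57 years, ~51.7% women, and
    survey weights summing to 324.6 million persons.
    """

    n: int = Field(default=7287, ge=1)
    target_population: float = Field(default=324.6e6, gt=0)
    prop_female: float = Field(default=0.517, ge=0, le=1)
    age_mean: float = 57.0
    age_sd: float = Field(default=10.0, gt=0)
    sbp_mean: float = 130.0
    sbp_sd: float = Field(default=18.0, gt=0)
    sbp_age_slope: float = 0.5
    tc_mean: float = 4.8
    tc_sd: float = Field(default=0.9, gt=0)
    ldl_given_tc_ratio: float = 0.62
    ldl_noise_sd: float = Field(default=0.35, gt=0)
    hdl_mean: float = 1.3
    hdl_sd: float = Field(default=0.3, gt=0)
    smoking_prob_male: float = Field(default=0.50, ge=0, le=1)
    smoking_prob_female: float = Field(default=0.05, ge=0, le=1)
    cvd_history_prob: float = Field(default=0.05, ge=0, le=1)
    diabetes_prob: float = Field(default=0.08, ge=0, le=1)
    statin_use_prob: float = Field(default=0.02, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check_age_window(self) -> "GeneratorConfig":
        if not AGE_MIN <= self.age_mean <= AGE_MAX:
            raise ValueError("age_mean must lie within the [40, 80] window")
        return self


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate ``config.n`` synthetic records as a cohort table.

    Ages follow a truncated normal on [40, 80]; SBP drifts linearly with
    age; LDL-C is drawn from TC with additive noise and then truncated to
    [1.8, 4.9).  Weights are uniform, summing to ``target_population``.
    Reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    female = rng.random(n) < config.prop_female
    sex = np.where(female, "F", "M")

    age = _truncated_normal(rng, config.age_mean, config.age_sd, AGE_MIN, AGE_MAX, n)
    sbp = (
        config.sbp_mean
        + config.sbp_age_slope * (age - config.age_mean)
        + rng.normal(0.0, config.sbp_sd, n)
    )
    sbp = np.clip(sbp, 80.0, 240.0)

    tc = np.clip(rng.normal(config.tc_mean, config.tc_sd, n), 2.5, 12.0)
    ldl = config.ldl_given_tc_ratio * tc + rng.normal(0.0, config.ldl_noise_sd, n)
    ldl = np.clip(ldl, LDL_MIN, np.nextafter(LDL_MAX, 0.0))
    tc = np.maximum(tc, ldl)  # total cholesterol cannot fall below its LDL fraction

    hdl = np.clip(rng.normal(config.hdl_mean, config.hdl_sd, n), 0.4, 4.0)

    smoke_p = np.where(female, config.smoking_prob_female, config.smoking_prob_male)
    smoker = rng.random(n) < smoke_p

    cvd_history = rng.random(n) < config.cvd_history_prob
    diabetes = rng.random(n) < config.diabetes_prob
    statin_use = rng.random(n) < config.statin_use_prob

    weight = np.full(n, config.target_population / n)

    return pd.DataFrame(
        {
            "id": [f"P{i:06d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "smoker": smoker,
            "sbp": sbp,
            "tc": tc,
            "ldl": ldl,
            "hdl": hdl,
            "weight": weight,
            "cvd_history": cvd_history,
            "diabetes": diabetes,
            "statin_use": statin_use,
        },
        columns=COHORT_COLUMNS,
    )


def apply_inclusion_filters(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the analytic inclusion criteria and tally exclusions.

    Kept records satisfy 40 <= age <= 80, 1.8 <= LDL-C < 4.9 mmol/L, and
    have no CVD history, no diabetes, and no prior statin use.  The tally
    partitions removed records by the first matching reason in
    :data:`EXCLUSION_ORDER`, so counts are reproducible when reasons
    co-occur.  Empty input yields empty output and an all-zero tally.
    """
    tally = {reason: 0 for reason in EXCLUSION_ORDER}
    if len(records) == 0:
        return records.copy(), tally

    reasons = {
        "age_outside_40_80": (records["age"] < AGE_MIN) | (records["age"] > AGE_MAX),
        "cvd_history": records["cvd_history"].astype(bool),
        "diabetes": records["diabetes"].astype(bool),
        "ldl_below_1.8": records["ldl"] < LDL_MIN,
        "ldl_at_or_above_4.9": records["ldl"] >= LDL_MAX,
        "statin_use": records["statin_use"].astype(bool),
    }

    excluded = np.zeros(len(records), dtype=bool)
    for reason in EXCLUSION_ORDER:
        hit = reasons[reason].to_numpy() & ~excluded
        tally[reason] = int(hit.sum())
        excluded |= hit

    kept = records.loc[~excluded].reset_index(drop=True)
    return kept, tally


def rescale_weights(records: pd.DataFrame, target_population: float) -> pd.DataFrame:
    """Rescale survey weights by one constant so they sum to ``target_population``.

    Relative weights are preserved exactly; the input frame is not mutated.
    """
    if len(records) == 0:
        raise ValueError("cannot rescale weights of an empty cohort")
    if target_population <= 0:
        raise ValueError(f"target_population must be positive, got {target_population}")
    total = float(records["weight"].sum())
    if total <= 0:
        raise ValueError("current weights must sum to a positive total")
    out = records.copy()
    out["weight"] = records["weight"] * (target_population / total)
    return out
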