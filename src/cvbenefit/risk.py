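"""Untreated 10-year CVD risk from a pluggable sex-specific survival model.

The functional form is the standard Cox-type 10-year risk
``1 - S0 ** exp(LP)`` with a mean-centred linear predictor, followed by a
sex-specific recalibration divisor that corrects systematic overestimation
in the target population (defaults 1.59 for men, 1.72 for women).

Coefficients are pluggable: a documented synthetic stand-in set ships with
the package (``data/default_risk_model.json``); users may supply their own
transcribed coefficient sets for realism.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "SexRiskModel",
    "RiskModelSpec",
    "RISK_STRATA",
    "load_risk_model",
    "default_risk_model",
    "linear_predictor",
    "predict_untreated_risk",
    "classify_risk",
]

#: Upper clip bound keeping iNNT finite and log-space operations defined.
RISK_CAP = 0.999

#: Risk strata: label -> [lower, upper) bounds as risk fractions.
RISK_STRATA = {
    "low": (0.0, 0.05),
    "borderline": (0.05, 0.075),
    "intermediate": (0.075, 0.10),
    "high": (0.10, 1.0),
}

Transform = Literal["identity", "log"]


class SexRiskModel(BaseModel):
    """Log-linear 10-year survival model for one sex."""

    coefficients: dict[str, float]
    covariate_means: dict[str, float]
    transforms: dict[str, Transform] = Field(default_factory=dict)
    baseline_survival_10y: float = Field(gt=0, lt=1)
    recalibration_divisor: float = Field(default=1.0, gt=0)

    @model_validator(mode="after")
    def _check_keys(self) -> "SexRiskModel":
        if set(self.coefficients) != set(self.covariate_means):
            raise ValueError(
                "coefficients and covariate_means must carry identical covariate keys"
            )
        extra = set(self.transforms) - set(self.coefficients)
        if extra:
            raise ValueError(f"transforms refer to unknown covariates: {sorted(extra)}")
        return self


class RiskModelSpec(BaseModel):
    """Sex-specific risk models keyed by 'M' and 'F'."""

    M: SexRiskModel
    F: SexRiskModel

    def for_sex(self, sex: str) -> SexRiskModel:
        if sex not in ("M", "F"):
            raise KeyError(f"sex must be 'M' or 'F', got {sex!r}")
        return getattr(self, sex)


def load_risk_model(path: str | Path) -> RiskModelSpec:
    """Load and schema-validate a risk-model spec from a JSON file."""
    with open(path, encoding="utf-8") as fh:
        return RiskModelSpec.model_validate(json.load(fh))


def default_risk_model() -> RiskModelSpec:
    """The synthetic stand-in coefficient set shipped with the package."""
    text = resources.files("cvbenefit").joinpath("data/default_risk_model.json").read_text()
    return RiskModelSpec.model_validate(json.loads(text))


def _apply_transform(values: np.ndarray, transform: Transform) -> np.ndarray:
    if transform == "log":
        return np.log(values)
    return values


def linear_predictor(records: pd.DataFrame, spec: RiskModelSpec) -> pd.Series:
    """Mean-centred linear predictor, per record, in log-hazard units.

    Computes ``sum_k beta_k * (t(x_k) - mean_k)`` over the covariates of
    each record's sex-specific model, where ``t`` is the declared
    per-covariate transform.  Boolean covariates are coerced to 0/1.
    Raises ``KeyError`` if a model covariate is absent from the table.
    """
    lp = np.zeros(len(records))
    sexes = records["sex"].to_numpy()
    for sex in ("M", "F"):
        mask = sexes == sex
        if not mask.any():
            continue
        model = spec.for_sex(sex)
        acc = np.zeros(int(mask.sum()))
        for name, beta in model.coefficients.items():
            if name not in records.columns:
                raise KeyError(f"covariate {name!r} missing from cohort table")
            x = records.loc[mask, name].to_numpy(dtype=float)
            x = _apply_transform(x, model.transforms.get(name, "identity"))
            acc += beta * (x - model.covariate_means[name])
        lp[mask] = acc
    return pd.Series(lp, index=records.index, name="linear_predictor")


def predict_untreated_risk(records: pd.DataFrame, spec: RiskModelSpec) -> pd.Series:
    """Recalibrated untreated 10-year CVD risk per record.

    Raw risk is ``1 - S0 ** exp(LP)``; the returned value is raw risk
    divided by the sex-specific recalibration divisor, clipped to
    [0, 0.999].
    """
    lp = linear_predictor(records, spec).to_numpy()
    sexes = records["sex"].to_numpy()
    risk = np.empty(len(records))
    for sex in ("M", "F"):
        mask = sexes == sex
        if not mask.any():
            continue
        model = spec.for_sex(sex)
        # exp(LP) in log space: survival^exp(LP) = exp(exp(LP) * ln S0)
        raw = 1.0 - np.exp(np.exp(lp[mask]) * math.log(model.baseline_survival_10y))
        risk[mask] = raw / model.recalibration_divisor
    return pd.Series(np.clip(risk, 0.0, RISK_CAP), index=records.index, name="untreated_risk")


def classify_risk(risk: float | np.ndarray | pd.Series) -> np.ndarray | str:
    """Assign each risk fraction to its stratum label.

    Strata are half-open with inclusive lower bounds: low [0, 5%),
    borderline [5%, 7.5%), intermediate [7.5%, 10%), high [10%, 100%).
    Scalar input returns a scalar label.
    """
    arr = np.asarray(risk, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.any((arr < 0) | (arr >= 1)):
        raise ValueError("risk must lie in [0, 1)")
    labels = np.empty(arr.shape, dtype=object)
    for label, (lo, hi) in RISK_STRATA.items():
        labels[(arr >= lo) & (arr < hi)] = label
    if scalar:
        return str(labels[0])
    if isinstance(risk, pd.Series):
        return pd.Series(labels, index=risk.index, name="risk_stratum")
    return labels
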