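"""Individualized benefit chain: LDL-C reduction -> overall RR -> iARR -> iNNT.

For each person the expected absolute LDL-C reduction is a fixed proportion
of baseline LDL-C; the relative risk per mmol/L of reduction is either a
constant or a function of baseline risk; the overall RR compounds the
per-unit RR over the achieved reduction (``rr_unit ** delta``, evaluated in
log space); the on-treatment risk is untreated risk times overall RR; and
the individual absolute risk reduction (iARR) is their difference.  The
individual NNT is ``1 / iARR``.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "TreatmentSpec",
    "delta_ldl",
    "rr_per_unit",
    "overall_rr",
    "compute_iarr",
    "compute_innt",
    "classify_benefit",
    "estimate_individuals",
    "ESTIMATE_COLUMNS",
]

ESTIMATE_COLUMNS = [
    "untreated_risk",
    "delta_ldl",
    "rr_unit",
    "rr_overall",
    "treated_risk",
    "iarr",
    "innt",
]


class RRInteraction(BaseModel):
    """RR per mmol/L as exp(intercept + slope * g(risk)) on a declared scale."""

    intercept: float
    slope: float
    scale: Literal["identity", "log", "logit"] = "identity"


class TreatmentSpec(BaseModel):
    """Proportional LDL-C reduction and RR-per-mmol/L specification.

    The default 40% reduction corresponds to moderate-intensity therapy;
    30% is the low-effect sensitivity setting.  The default constant RR of
    0.78 per mmol/L is a documented package fixture, not a transcribed
    meta-analysis estimate; substitute your own value for realism.
    """

    ldl_reduction_prop: float = Field(default=0.40, gt=0, lt=1)
    rr_mode: Literal["constant", "risk_interaction"] = "constant"
    rr_constant: float = Field(default=0.78, gt=0, le=1)
    rr_interaction: RRInteraction | None = None

    @model_validator(mode="after")
    def _check_interaction(self) -> "TreatmentSpec":
        if self.rr_mode == "risk_interaction" and self.rr_interaction is None:
            raise ValueError("rr_mode 'risk_interaction' requires rr_interaction params")
        return self


def delta_ldl(baseline_ldl: float | np.ndarray, spec: TreatmentSpec) -> float | np.ndarray:
    """Expected absolute LDL-C reduction (mmol/L): baseline times the proportion."""
    arr = np.asarray(baseline_ldl, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("baseline LDL-C must be positive")
    out = arr * spec.ldl_reduction_prop
    return float(out) if out.ndim == 0 else out


def rr_per_unit(untreated_risk: float | np.ndarray, spec: TreatmentSpec) -> float | np.ndarray:
    """Relative risk of CVD per mmol/L of LDL-C reduction.

    Constant mode ignores risk; interaction mode evaluates
    ``exp(intercept + slope * g(risk))`` with g per the declared scale,
    clipped into (0, 1].
    """
    arr = np.asarray(untreated_risk, dtype=float)
    if np.any((arr < 0) | (arr >= 1)):
        raise ValueError("untreated risk must lie in [0, 1)")
    if spec.rr_mode == "constant":
        out = np.full(arr.shape, spec.rr_constant)
    else:
        params = spec.rr_interaction
        assert params is not None
        if params.scale == "log":
            g = np.log(np.maximum(arr, 1e-12))
        elif params.scale == "logit":
            clipped = np.clip(arr, 1e-12, 1 - 1e-12)
            g = np.log(clipped / (1 - clipped))
        else:
            g = arr
        out = np.clip(np.exp(params.intercept + params.slope * g), 1e-12, 1.0)
    return float(out) if out.ndim == 0 else out


def overall_rr(delta: float | np.ndarray, rr_unit: float | np.ndarray) -> float | np.ndarray:
    """Overall RR of treatment: rr_unit ** delta, computed in log space."""
    d = np.asarray(delta, dtype=float)
    r = np.asarray(rr_unit, dtype=float)
    if np.any(d < 0):
        raise ValueError("LDL-C reduction must be non-negative")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("rr_unit must lie in (0, 1]")
    out = np.exp(d * np.log(r))
    return float(out) if out.ndim == 0 else out


def compute_iarr(
    untreated_risk: float | np.ndarray, rr_overall: float | np.ndarray
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """On-treatment risk and iARR: (risk * RR, risk - risk * RR)."""
    risk = np.asarray(untreated_risk, dtype=float)
    rr = np.asarray(rr_overall, dtype=float)
    if np.any((risk < 0) | (risk >= 1)):
        raise ValueError("untreated risk must lie in [0, 1)")
    if np.any((rr <= 0) | (rr > 1)):
        raise ValueError("rr_overall must lie in (0, 1]")
    treated = risk * rr
    iarr = risk - treated
    if treated.ndim == 0:
        return float(treated), float(iarr)
    return treated, iarr


def compute_innt(iarr: float | np.ndarray) -> float | np.ndarray:
    """Individual NNT = 1/iARR, unrounded.

    Raises ``ValueError`` for non-positive iARR (a person with no modeled
    benefit has no defined iNNT); the vectorized path in
    :func:`estimate_individuals` emits NaN for such persons instead.
    """
    arr = np.asarray(iarr, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("iNNT undefined: iARR must be positive")
    out = 1.0 / arr
    return float(out) if out.ndim == 0 else out


def classify_benefit(
    iarr: float | np.ndarray | pd.Series,
    high_threshold: float,
    moderate_threshold: float,
) -> np.ndarray | str | pd.Series:
    """Benefit category: high (iarr >= high), moderate (>= moderate), else low."""
    if moderate_threshold > high_threshold:
        raise ValueError("moderate_threshold must not exceed high_threshold")
    arr = np.asarray(iarr, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    labels = np.where(
        arr >= high_threshold, "high", np.where(arr >= moderate_threshold, "moderate", "low")
    ).astype(object)
    if scalar:
        return str(labels[0])
    if isinstance(iarr, pd.Series):
        return pd.Series(labels, index=iarr.index, name="benefit_category")
    return labels


def estimate_individuals(
    records: pd.DataFrame, untreated_risk: pd.Series, spec: TreatmentSpec
) -> pd.DataFrame:
    """Per-person benefit estimates, one row per cohort record.

    Returns a frame with columns ``untreated_risk, delta_ldl, rr_unit,
    rr_overall, treated_risk, iarr, innt`` aligned with ``records``; innt
    is NaN where iARR is zero.
    """
    risk = untreated_risk.to_numpy(dtype=float)
    d = delta_ldl(records["ldl"].to_numpy(dtype=float), spec)
    ru = rr_per_unit(risk, spec)
    rr = overall_rr(d, ru)
    treated, iarr = compute_iarr(risk, rr)
    with np.errstate(divide="ignore"):
        innt = np.where(iarr > 0, 1.0 / np.where(iarr > 0, iarr, 1.0), np.nan)
    return pd.DataFrame(
        {
            "untreated_risk": risk,
            "delta_ldl": d,
            "rr_unit": ru,
            "rr_overall": rr,
            "treated_risk": treated,
            "iarr": iarr,
            "innt": innt,
        },
        index=records.index,
        columns=ESTIMATE_COLUMNS,
    )
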