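"""Eligibility strategies and benefit-threshold calibration.

Two principles set benefit (iARR) thresholds:

1. Comparable event prevention — scan candidate thresholds for the one
   whose weighted events averted is closest to the events averted by a
   reference risk-threshold strategy.
2. Minimum benefit expansion — use the minimum iARR observed among the
   risk-eligible group, so every risk-eligible person remains eligible.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

__all__ = [
    "StrategyDefinition",
    "CalibrationResult",
    "eligible",
    "minimum_benefit_threshold",
    "calibrate_benefit_threshold",
]


class StrategyDefinition(BaseModel):
    """One eligibility rule: treat when risk or iARR meets a threshold."""

    kind: Literal["risk_threshold", "benefit_threshold"]
    threshold: float = Field(gt=0, lt=1)
    label: str = ""

    def describe(self) -> str:
        if self.label:
            return self.label
        quantity = "risk" if self.kind == "risk_threshold" else "iARR"
        return f"{quantity} >= {self.threshold:.1%}"


class CalibrationResult(BaseModel):
    """Outcome of the comparable-event-prevention threshold search."""

    threshold: float
    achieved_events: float
    target_events: float
    grid: list[float]
    rounded_threshold: float  # percent, one decimal

    @property
    def strategy(self) -> StrategyDefinition:
        return StrategyDefinition(
            kind="benefit_threshold",
            threshold=self.threshold,
            label=f"calibrated iARR >= {self.rounded_threshold}%",
        )


def eligible(estimates: pd.DataFrame, strategy: StrategyDefinition) -> pd.Series:
    """Boolean eligibility indicator per record (thresholds inclusive)."""
    if strategy.kind == "risk_threshold":
        values = estimates["untreated_risk"]
    else:
        values = estimates["iarr"]
    return (values >= strategy.threshold).rename("eligible")


def minimum_benefit_threshold(estimates: pd.DataFrame, risk_eligible: pd.Series) -> float:
    """Minimum iARR observed among risk-eligible records."""
    if len(estimates) != len(risk_eligible):
        raise ValueError("estimates and eligibility indicator are misaligned")
    selected = estimates.loc[risk_eligible.to_numpy(dtype=bool), "iarr"]
    if selected.empty:
        raise ValueError("no risk-eligible records: minimum benefit undefined")
    return float(selected.min())


def _events_at_threshold(iarr: np.ndarray, weights: np.ndarray, threshold: float) -> float:
    mask = iarr >= threshold
    return float(np.sum(weights[mask] * iarr[mask]))


def calibrate_benefit_threshold(
    estimates: pd.DataFrame,
    weights: pd.Series | np.ndarray,
    target_events: float,
    tolerance: float | None = None,
) -> CalibrationResult:
    """Find the iARR threshold whose weighted events averted best matches a target.

    The candidate grid is the sorted distinct iARR values, their midpoints,
    and one value just above the maximum (the empty strategy), so every
    threshold-consistent eligible set is reachable.  Ties in achieved
    events are broken toward the higher threshold (fewer people treated).

    Raises ``ValueError`` when the target exceeds the events averted with
    everyone treated (unattainable), or when ``tolerance`` is given and the
    best achievable match misses the target by more than it.
    """
    if target_events < 0:
        raise ValueError("target_events must be non-negative")
    iarr = estimates["iarr"].to_numpy(dtype=float)
    w = np.asarray(weights, dtype=float)
    if iarr.shape != w.shape:
        raise ValueError("estimates and weights are misaligned")
    if not np.all(np.isfinite(iarr)):
        raise ValueError("iARR values must be finite for calibration")

    distinct = np.unique(iarr)
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    above_max = np.nextafter(distinct[-1], np.inf)
    grid = np.concatenate([distinct, midpoints, [above_max]])
    grid.sort()

    total_events = _events_at_threshold(iarr, w, grid[0])
    if target_events > total_events:
        raise ValueError(
            f"target of {target_events:.6g} events is unattainable: treating everyone "
            f"averts only {total_events:.6g}"
        )

    achieved = np.array([_events_at_threshold(iarr, w, t) for t in grid])
    gaps = np.abs(achieved - target_events)
    best_gap = gaps.min()
    # ties broken toward the higher threshold: grid is sorted ascending
    best_idx = int(np.flatnonzero(gaps == best_gap).max())
    threshold = float(grid[best_idx])

    if tolerance is not None and best_gap > tolerance:
        raise ValueError(
            f"best achievable match misses the target by {best_gap:.6g} events "
            f"(> tolerance {tolerance:.6g})"
        )

    return CalibrationResult(
        threshold=threshold,
        achieved_events=float(achieved[best_idx]),
        target_events=float(target_events),
        grid=[float(t) for t in grid],
        rounded_threshold=round(threshold * 100.0, 1),
    )
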