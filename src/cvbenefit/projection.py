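"""Survey-weighted population projections for an eligibility strategy.

Events averted are computed deterministically as the weighted sum of
individual absolute risk reductions (expected events, not simulated
Bernoulli outcomes); bootstrap resampling of persons (weights carried)
captures sampling uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import StrategyDefinition, eligible

__all__ = [
    "StrategyResult",
    "events_averted",
    "average_nnt",
    "max_innt",
    "summarize_iarr",
    "weighted_median",
    "bootstrap_ci",
    "project_to_population",
    "evaluate_strategy",
]

BOOTSTRAP_STATISTICS = ("events_averted", "average_nnt", "eligible_persons", "eligible_prop")


@dataclass
class StrategyResult:
    """Population- and individual-level outcomes for one strategy."""

    label: str
    eligible_persons: float
    eligible_prop: float
    events_averted: float
    average_nnt: float
    max_innt: float
    iarr_median: float
    iarr_min: float
    iarr_max: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {
            "strategy": self.label,
            "eligible_millions": project_to_population(self.eligible_persons, "millions"),
            "eligible_percent": round(self.eligible_prop * 100.0, 1),
            "events_averted_thousands": project_to_population(self.events_averted, "thousands"),
            "average_nnt": round(self.average_nnt) if np.isfinite(self.average_nnt) else np.nan,
            "max_innt": round(self.max_innt) if np.isfinite(self.max_innt) else np.nan,
            "iarr_median_percent": round(self.iarr_median * 100.0, 1),
            "iarr_min_percent": round(self.iarr_min * 100.0, 1),
            "iarr_max_percent": round(self.iarr_max * 100.0, 1),
        }
        for name, (lo, hi) in self.ci.items():
            row[f"{name}_ci_lower"] = lo
            row[f"{name}_ci_upper"] = hi
        return row


def _aligned(*arrays) -> None:
    lengths = {len(a) for a in arrays}
    if len(lengths) > 1:
        raise ValueError("input vectors are misaligned")


def events_averted(weights, iarrs, eligible_mask) -> float:
    """Weighted 10-year events averted: sum of weight * iARR over eligible."""
    w = np.asarray(weights, dtype=float)
    a = np.asarray(iarrs, dtype=float)
    m = np.asarray(eligible_mask, dtype=bool)
    _aligned(w, a, m)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(w[m] * a[m]))


def average_nnt(eligible_persons: float, events: float) -> float:
    """Population-average NNT: weighted eligible persons per event averted."""
    if events <= 0:
        raise ValueError("average NNT undefined: no events averted")
    return eligible_persons / events


def max_innt(iarrs, eligible_mask) -> float:
    """iNNT of the least-benefiting eligible person: 1 / min eligible iARR."""
    a = np.asarray(iarrs, dtype=float)
    m = np.asarray(eligible_mask, dtype=bool)
    _aligned(a, m)
    if not m.any():
        raise ValueError("max iNNT undefined: empty eligible set")
    min_iarr = float(a[m].min())
    if min_iarr <= 0:
        raise ValueError("max iNNT undefined: eligible person with non-positive iARR")
    return 1.0 / min_iarr


def weighted_median(values, weights) -> float:
    """Lower weighted median: smallest value whose cumulative weight >= half."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    _aligned(v, w)
    if len(v) == 0:
        raise ValueError("weighted median of an empty set")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    idx = int(np.searchsorted(cum, cum[-1] / 2.0, side="left"))
    return float(v[order][idx])


def summarize_iarr(iarrs, weights, eligible_mask) -> tuple[float, float, float]:
    """(weighted median, min, max) of iARR over the eligible set."""
    a = np.asarray(iarrs, dtype=float)
    w = np.asarray(weights, dtype=float)
    m = np.asarray(eligible_mask, dtype=bool)
    _aligned(a, w, m)
    if not m.any():
        raise ValueError("iARR summary undefined: empty eligible set")
    sel, wsel = a[m], w[m]
    return weighted_median(sel, wsel), float(sel.min()), float(sel.max())


def _statistic(name: str, w: np.ndarray, a: np.ndarray, m: np.ndarray) -> float:
    if name == "events_averted":
        return float(np.sum(w[m] * a[m]))
    if name == "eligible_persons":
        return float(w[m].sum())
    if name == "eligible_prop":
        return float(w[m].sum() / w.sum())
    if name == "average_nnt":
        events = float(np.sum(w[m] * a[m]))
        if events <= 0:
            return np.nan
        return float(w[m].sum()) / events
    raise ValueError(f"unknown statistic {name!r}; choose from {BOOTSTRAP_STATISTICS}")


def bootstrap_ci(
    estimates: pd.DataFrame,
    weights,
    strategy: StrategyDefinition,
    statistic: str,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% CI from person-level resampling with replacement.

    Weights travel with their records.  Replicates where the statistic is
    undefined (e.g., zero events averted) are dropped from the percentiles;
    reproducible given ``seed``.
    """
    if reps < 2:
        raise ValueError("bootstrap requires at least 2 replicates")
    w = np.asarray(weights, dtype=float)
    a = estimates["iarr"].to_numpy(dtype=float)
    values = (
        estimates["untreated_risk"].to_numpy(dtype=float)
        if strategy.kind == "risk_threshold"
        else a
    )
    _aligned(w, a, values)
    n = len(w)
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, n, n)
        m = values[idx] >= strategy.threshold
        out[r] = _statistic(statistic, w[idx], a[idx], m)
    valid = out[np.isfinite(out)]
    if len(valid) == 0:
        raise ValueError("all bootstrap replicates were degenerate")
    lower, upper = np.percentile(valid, [2.5, 97.5])
    return float(lower), float(upper)


def project_to_population(value: float, unit: str) -> float:
    """Express a weighted person count in display units, one decimal."""
    if value < 0:
        raise ValueError("population values must be non-negative")
    divisors = {"thousands": 1e3, "millions": 1e6}
    if unit not in divisors:
        raise ValueError(f"unit must be one of {sorted(divisors)}")
    return round(value / divisors[unit], 1)


def evaluate_strategy(
    estimates: pd.DataFrame,
    weights,
    strategy: StrategyDefinition,
    bootstrap_reps: int = 0,
    seed: int = 0,
    ci_statistics: tuple[str, ...] = ("events_averted", "average_nnt", "eligible_persons"),
) -> StrategyResult:
    """Full projection for one strategy, optionally with bootstrap CIs."""
    w = np.asarray(weights, dtype=float)
    mask = eligible(estimates, strategy).to_numpy(dtype=bool)
    a = estimates["iarr"].to_numpy(dtype=float)
    persons = float(w[mask].sum())
    events = events_averted(w, a, mask)
    median, amin, amax = summarize_iarr(a, w, mask)
    result = StrategyResult(
        label=strategy.describe(),
        eligible_persons=persons,
        eligible_prop=persons / float(w.sum()),
        events_averted=events,
        average_nnt=average_nnt(persons, events) if events > 0 else np.nan,
        max_innt=max_innt(a, mask),
        iarr_median=median,
        iarr_min=amin,
        iarr_max=amax,
    )
    if bootstrap_reps:
        for name in ci_statistics:
            result.ci[name] = bootstrap_ci(
                estimates, w, strategy, name, reps=bootstrap_reps, seed=seed
            )
    return result
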