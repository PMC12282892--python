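"""Agreement between eligibility strategies: overlap, reclassification
flows, subgroup efficiency, and weighted group characteristics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConcordanceResult",
    "cross_tabulate",
    "flow_matrix",
    "subgroup_efficiency",
    "compare_characteristics",
]

CONTINUOUS_COVARIATES = ["age", "sbp", "tc", "ldl", "hdl"]
BINARY_COVARIATES = ["smoker"]


@dataclass(frozen=True)
class ConcordanceResult:
    """Weighted 2x2 agreement between two eligibility indicators."""

    both: float
    only_a: float
    only_b: float
    neither: float

    @property
    def either(self) -> float:
        return self.both + self.only_a + self.only_b

    @property
    def overlap_prop(self) -> float:
        """Share of the either-eligible population eligible under both.

        NaN when nobody is eligible under either strategy.
        """
        if self.either == 0:
            return float("nan")
        return self.both / self.either

    def to_dict(self) -> dict[str, float]:
        return {
            "both": self.both,
            "only_a": self.only_a,
            "only_b": self.only_b,
            "neither": self.neither,
            "either": self.either,
            "overlap_prop": self.overlap_prop,
        }


def cross_tabulate(elig_a, elig_b, weights) -> ConcordanceResult:
    """Weighted counts of the four agreement cells between two strategies."""
    a = np.asarray(elig_a, dtype=bool)
    b = np.asarray(elig_b, dtype=bool)
    w = np.asarray(weights, dtype=float)
    if not (len(a) == len(b) == len(w)):
        raise ValueError("eligibility indicators and weights are misaligned")
    return ConcordanceResult(
        both=float(w[a & b].sum()),
        only_a=float(w[a & ~b].sum()),
        only_b=float(w[~a & b].sum()),
        neither=float(w[~a & ~b].sum()),
    )


def flow_matrix(risk_strata, benefit_categories, weights) -> pd.DataFrame:
    """Weighted contingency table of risk stratum (rows) by benefit category
    (columns); margins are conserved by construction."""
    strata = pd.Series(np.asarray(risk_strata, dtype=object), name="risk_stratum")
    cats = pd.Series(np.asarray(benefit_categories, dtype=object), name="benefit_category")
    w = np.asarray(weights, dtype=float)
    if not (len(strata) == len(cats) == len(w)):
        raise ValueError("strata, categories, and weights are misaligned")
    if strata.isna().any() or cats.isna().any():
        raise ValueError("every record needs one risk stratum and one benefit category")
    frame = pd.DataFrame({"risk_stratum": strata, "benefit_category": cats, "weight": w})
    table = frame.pivot_table(
        index="risk_stratum",
        columns="benefit_category",
        values="weight",
        aggfunc="sum",
        fill_value=0.0,
    )
    stratum_order = [s for s in ("low", "borderline", "intermediate", "high") if s in table.index]
    category_order = [c for c in ("low", "moderate", "high") if c in table.columns]
    if stratum_order and category_order:
        extra_rows = [s for s in table.index if s not in stratum_order]
        extra_cols = [c for c in table.columns if c not in category_order]
        table = table.reindex(index=stratum_order + extra_rows, columns=category_order + extra_cols)
    return table


def subgroup_efficiency(
    elig_risk, elig_benefit, elig_expansion, estimates: pd.DataFrame, weights
) -> pd.DataFrame:
    """Weighted persons, events averted, and average NNT in the concordance
    subgroups: both criteria, risk-only, benefit-only, and the group added
    only by the expanded (minimum-benefit) threshold.

    The expansion set must contain the union of the risk- and
    benefit-eligible sets.  NNT is NaN for empty subgroups.
    """
    r = np.asarray(elig_risk, dtype=bool)
    b = np.asarray(elig_benefit, dtype=bool)
    e = np.asarray(elig_expansion, dtype=bool)
    w = np.asarray(weights, dtype=float)
    a = estimates["iarr"].to_numpy(dtype=float)
    if not (len(r) == len(b) == len(e) == len(w) == len(a)):
        raise ValueError("inputs are misaligned")
    if np.any((r | b) & ~e):
        raise ValueError("expansion set must contain the union of risk- and benefit-eligible sets")

    masks = {
        "both": r & b,
        "risk_only": r & ~b,
        "benefit_only": ~r & b,
        "expansion_only": e & ~r & ~b,
    }
    rows = []
    for name, mask in masks.items():
        persons = float(w[mask].sum())
        events = float(np.sum(w[mask] * a[mask]))
        rows.append(
            {
                "subgroup": name,
                "persons": persons,
                "events_averted": events,
                "average_nnt": persons / events if events > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("subgroup")


def _weighted_mean_sd(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    mean = float(np.average(values, weights=weights))
    # frequency-weight convention: weights are person counts
    var = float(np.average((values - mean) ** 2, weights=weights))
    return mean, float(np.sqrt(var))


def compare_characteristics(
    records: pd.DataFrame,
    group_a,
    group_b,
    continuous: list[str] | None = None,
    binary: list[str] | None = None,
    labels: tuple[str, str] = ("group_a", "group_b"),
) -> pd.DataFrame:
    """Weighted descriptive comparison of two groups (no inferential tests).

    Continuous covariates get weighted mean and SD; binary covariates (and
    sex) get weighted percentages.  Groups are boolean masks over
    ``records``; both must be nonempty.
    """
    a = np.asarray(group_a, dtype=bool)
    b = np.asarray(group_b, dtype=bool)
    if len(a) != len(records) or len(b) != len(records):
        raise ValueError("group masks are misaligned with records")
    if not a.any() or not b.any():
        raise ValueError("both groups must be nonempty")
    continuous = CONTINUOUS_COVARIATES if continuous is None else continuous
    binary = BINARY_COVARIATES if binary is None else binary

    w = records["weight"].to_numpy(dtype=float)
    rows = []
    for mask, label in ((a, labels[0]), (b, labels[1])):
        row: dict[str, float | str] = {"group": label, "persons": float(w[mask].sum())}
        for cov in continuous:
            mean, sd = _weighted_mean_sd(records.loc[mask, cov].to_numpy(dtype=float), w[mask])
            row[f"{cov}_mean"] = mean
            row[f"{cov}_sd"] = sd
        for cov in binary:
            vals = records.loc[mask, cov].to_numpy(dtype=float)
            row[f"{cov}_percent"] = float(np.average(vals, weights=w[mask])) * 100.0
        if "sex" in records.columns:
            female = (records.loc[mask, "sex"] == "F").to_numpy(dtype=float)
            row["female_percent"] = float(np.average(female, weights=w[mask])) * 100.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
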