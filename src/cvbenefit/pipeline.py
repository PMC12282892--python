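"""End-to-end orchestration: simulate -> filter -> estimate -> calibrate ->
compare -> report, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .benefit import classify_benefit, estimate_individuals
from .calibration import (
    StrategyDefinition,
    calibrate_benefit_threshold,
    eligible,
    minimum_benefit_threshold,
)
from .cohort import apply_inclusion_filters, generate_cohort, rescale_weights
from .concordance import (
    compare_characteristics,
    cross_tabulate,
    flow_matrix,
    subgroup_efficiency,
)
from .config import CalibratedBenefitDirective, MinimumBenefitDirective, RunConfig
from .io import write_cohort_csv, write_estimates_csv
from .projection import evaluate_strategy
from .risk import classify_risk, default_risk_model, load_risk_model

__all__ = ["run_pipeline", "resolve_strategies", "PipelineError"]

log = logging.getLogger("cvbenefit")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def resolve_strategies(
    config: RunConfig, estimates: pd.DataFrame, weights: pd.Series
) -> tuple[list[StrategyDefinition], list[dict]]:
    """Turn strategy specs into concrete thresholds, calibrating as needed.

    Returns the resolved strategies plus a list of calibration records
    (JSON-serializable) for the strategies that required one.
    """
    resolved: list[StrategyDefinition] = []
    calibrations: list[dict] = []
    for spec in config.strategies:
        if isinstance(spec, StrategyDefinition):
            resolved.append(spec)
            continue
        reference = StrategyDefinition(
            kind="risk_threshold",
            threshold=(
                spec.match_risk_threshold
                if isinstance(spec, CalibratedBenefitDirective)
                else spec.from_risk_threshold
            ),
        )
        risk_mask = eligible(estimates, reference)
        if isinstance(spec, CalibratedBenefitDirective):
            target = float(
                np.sum(weights.to_numpy()[risk_mask] * estimates["iarr"].to_numpy()[risk_mask])
            )
            result = calibrate_benefit_threshold(estimates, weights, target)
            threshold = result.threshold
            calibrations.append(
                {
                    "label": spec.label,
                    "match_risk_threshold": reference.threshold,
                    "threshold": result.threshold,
                    "rounded_threshold_percent": result.rounded_threshold,
                    "achieved_events": result.achieved_events,
                    "target_events": result.target_events,
                }
            )
        else:
            threshold = minimum_benefit_threshold(estimates, risk_mask)
            calibrations.append(
                {
                    "label": spec.label,
                    "from_risk_threshold": reference.threshold,
                    "threshold": threshold,
                    "rounded_threshold_percent": round(threshold * 100.0, 1),
                }
            )
        resolved.append(
            StrategyDefinition(
                kind="benefit_threshold",
                threshold=threshold,
                label=spec.label or f"iARR >= {threshold:.2%}",
            )
        )
    return resolved, calibrations


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return the run manifest.

    Identical config and seed produce byte-identical numeric outputs.  Any
    stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir if out_dir is not None else config.output)
    out.mkdir(parents=True, exist_ok=True)

    try:
        spec = load_risk_model(config.risk_model) if config.risk_model else default_risk_model()
    except FileNotFoundError as exc:
        raise PipelineError("load_risk_model", str(exc)) from exc

    try:
        raw = generate_cohort(config.generator)
        log.info("simulate: generated %d records", len(raw))
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    try:
        kept, tally = apply_inclusion_filters(raw)
        log.info("filter: kept %d of %d records; exclusions %s", len(kept), len(raw), tally)
        if kept.empty:
            raise ValueError("no records satisfy the inclusion criteria")
        cohort = rescale_weights(kept, config.generator.target_population)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc

    try:
        from .risk import predict_untreated_risk

        risk = predict_untreated_risk(cohort, spec)
        estimates = estimate_individuals(cohort, risk, config.treatment)
        log.info("estimate: %d person-level estimates", len(estimates))
    except Exception as exc:
        raise PipelineError("estimate", str(exc)) from exc

    weights = cohort["weight"]
    try:
        strategies, calibrations = resolve_strategies(config, estimates, weights)
        if not strategies:
            raise ValueError("config defines no strategies")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("calibrate", str(exc)) from exc

    try:
        results = [
            evaluate_strategy(
                estimates,
                weights,
                strat,
                bootstrap_reps=config.bootstrap.reps,
                seed=config.bootstrap.seed + i,
            )
            for i, strat in enumerate(strategies)
        ]
        results_table = pd.DataFrame([r.to_row() for r in results])
    except Exception as exc:
        raise PipelineError("compare", str(exc)) from exc

    try:
        report_tables = _concordance_report(cohort, estimates, strategies, weights)
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc

    paths: dict[str, Path] = {}
    paths["cohort"] = write_cohort_csv(cohort, out / "cohort.csv")
    paths["estimates"] = write_estimates_csv(cohort, estimates, out / "estimates.csv")
    results_table.to_csv(out / "results.csv", index=False, lineterminator="\n")
    paths["results"] = out / "results.csv"
    (out / "calibration.json").write_text(json.dumps(calibrations, indent=2) + "\n")
    paths["calibration"] = out / "calibration.json"
    for name, table in report_tables.items():
        table.to_csv(out / f"{name}.csv", lineterminator="\n")
        paths[name] = out / f"{name}.csv"

    manifest = {
        "version": __version__,
        "config": config.model_dump(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.generator.seed,
        "records_generated": len(raw),
        "records_kept": len(cohort),
        "exclusion_tally": tally,
        "outputs": {name: _sha256(p) for name, p in paths.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _concordance_report(
    cohort: pd.DataFrame,
    estimates: pd.DataFrame,
    strategies: list[StrategyDefinition],
    weights: pd.Series,
) -> dict[str, pd.DataFrame]:
    """Concordance tables for the first risk and benefit strategies found."""
    tables: dict[str, pd.DataFrame] = {}
    risk_strats = [s for s in strategies if s.kind == "risk_threshold"]
    benefit_strats = [s for s in strategies if s.kind == "benefit_threshold"]
    if not risk_strats or not benefit_strats:
        return tables

    w = weights.to_numpy(dtype=float)
    risk_mask = eligible(estimates, risk_strats[0]).to_numpy()
    benefit_mask = eligible(estimates, benefit_strats[0]).to_numpy()

    conc = cross_tabulate(risk_mask, benefit_mask, w)
    tables["concordance"] = pd.DataFrame([conc.to_dict()])

    thresholds = sorted({s.threshold for s in benefit_strats}, reverse=True)
    high = thresholds[0]
    moderate = thresholds[1] if len(thresholds) > 1 else high
    strata = classify_risk(estimates["untreated_risk"])
    categories = classify_benefit(estimates["iarr"], high, moderate)
    tables["flows"] = flow_matrix(strata, categories, w)

    expansion_mask = risk_mask | benefit_mask
    if len(benefit_strats) > 1:
        expansion_mask = expansion_mask | eligible(estimates, benefit_strats[-1]).to_numpy()
    tables["subgroups"] = subgroup_efficiency(risk_mask, benefit_mask, expansion_mask, estimates, w)

    risk_only = risk_mask & ~benefit_mask
    benefit_only = benefit_mask & ~risk_mask
    if risk_only.any() and benefit_only.any():
        tables["characteristics"] = compare_characteristics(
            cohort, benefit_only, risk_only, labels=("benefit_only", "risk_only")
        )
    return tables
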