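"""Run configuration: one validated document binding all pipeline stages."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Annotated, Literal, Union

import yaml
from pydantic import BaseModel, Field

from .benefit import TreatmentSpec
from .calibration import StrategyDefinition
from .cohort import GeneratorConfig

__all__ = [
    "RunConfig",
    "BootstrapConfig",
    "CalibratedBenefitDirective",
    "MinimumBenefitDirective",
    "load_run_config",
    "default_run_config",
]


class CalibratedBenefitDirective(BaseModel):
    """Calibrate an iARR threshold to match the events averted by a
    risk-threshold strategy (comparable event prevention)."""

    kind: Literal["calibrated_benefit"] = "calibrated_benefit"
    match_risk_threshold: float = Field(gt=0, lt=1)
    label: str = ""


class MinimumBenefitDirective(BaseModel):
    """Expand eligibility with the minimum iARR observed among those
    eligible under a risk threshold (minimum benefit expansion)."""

    kind: Literal["minimum_benefit"] = "minimum_benefit"
    from_risk_threshold: float = Field(gt=0, lt=1)
    label: str = ""


StrategySpec = Annotated[
    Union[StrategyDefinition, CalibratedBenefitDirective, MinimumBenefitDirective],
    Field(discriminator="kind"),
]


class BootstrapConfig(BaseModel):
    reps: int = Field(default=200, ge=2)
    seed: int = 0


class RunConfig(BaseModel):
    """End-to-end pipeline configuration."""

    generator: GeneratorConfig = GeneratorConfig()
    risk_model: str | None = None  # path to a risk-model JSON; None = packaged default
    treatment: TreatmentSpec = TreatmentSpec()
    strategies: list[StrategySpec] = Field(default_factory=list)
    bootstrap: BootstrapConfig = BootstrapConfig()
    output: str = "results"


def default_run_config() -> RunConfig:
    """Primary-analysis layout: high-risk threshold, the benefit threshold
    calibrated to match it, and the minimum-benefit expansion."""
    return RunConfig(
        strategies=[
            StrategyDefinition(kind="risk_threshold", threshold=0.10, label="high_risk"),
            CalibratedBenefitDirective(match_risk_threshold=0.10, label="high_benefit"),
            MinimumBenefitDirective(from_risk_threshold=0.10, label="minimum_benefit"),
        ]
    )


def load_run_config(path: str | Path) -> RunConfig:
    """Load a JSON or YAML run configuration and validate it."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return RunConfig.model_validate(data)
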