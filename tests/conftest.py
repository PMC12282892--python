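import numpy as np
import pandas as pd
import pytest

from cvbenefit import (
    GeneratorConfig,
    TreatmentSpec,
    apply_inclusion_filters,
    default_risk_model,
    estimate_individuals,
    generate_cohort,
    predict_untreated_risk,
    rescale_weights,
)


def make_cohort_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a cohort table from partial row dicts, filling sane defaults."""
    defaults = {
        "age": 55.0,
        "sex": "M",
        "smoker": False,
        "sbp": 130.0,
        "tc": 5.0,
        "ldl": 3.0,
        "hdl": 1.3,
        "weight": 1.0,
        "cvd_history": False,
        "diabetes": False,
        "statin_use": False,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {"id": f"R{i}", **defaults, **row}
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def risk_model():
    return default_risk_model()


@pytest.fixture(scope="session")
def default_cohort():
    """Filtered, weight-rescaled synthetic cohort under the default generator."""
    config = GeneratorConfig(n=3000, seed=42)
    kept, _ = apply_inclusion_filters(generate_cohort(config))
    return rescale_weights(kept, config.target_population)


@pytest.fixture(scope="session")
def default_estimates(default_cohort, risk_model):
    risk = predict_untreated_risk(default_cohort, risk_model)
    return estimate_individuals(default_cohort, risk, TreatmentSpec())
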