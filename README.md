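# cvbenefit

Compare two strategies for selecting adults for statin therapy in primary
prevention of cardiovascular disease (CVD):

1. **Absolute risk thresholds** — treat everyone whose predicted 10-year
   CVD risk meets a cut-off (e.g., ≥ 10%).
2. **Individualized benefit** — treat everyone whose predicted individual
   absolute risk reduction (iARR) from LDL-C lowering meets a cut-off,
   where iARR = untreated risk − on-treatment risk and the treatment
   effect compounds a per-mmol/L relative risk over the expected LDL-C
   reduction (`RR_unit ** ΔLDL`).

The package provides:

- a **synthetic cohort generator** (ages 40–80, LDL-C in [1.8, 4.9)
  mmol/L, survey weights scaling to a target population) so every stage is
  testable without external data;
- a pluggable sex-specific **risk engine** (Cox-type 10-year risk
  `1 − S0^exp(LP)` with sex-specific recalibration divisors, defaults 1.59
  for men / 1.72 for women) and risk strata (low / borderline /
  intermediate / high);
- the **benefit engine** (ΔLDL-C, RR per mmol/L — constant or
  risk-interacting — overall RR, on-treatment risk, iARR, iNNT = 1/iARR);
- **threshold calibration**: find the iARR cut-off whose weighted events
  averted matches a risk strategy's (comparable event prevention), or
  expand eligibility with the minimum iARR observed among the
  risk-eligible (minimum benefit expansion);
- **population projection**: weighted eligible counts and proportions,
  events averted (Σ weight × iARR), average NNT, maximum iNNT, iARR
  median/min/max, and percentile bootstrap 95% CIs;
- **concordance reporting**: weighted 2×2 overlap between strategies,
  risk-stratum × benefit-category flow tables, subgroup efficiency
  (both / risk-only / benefit-only / expansion-only NNTs), and weighted
  group characteristics.

The shipped risk-model coefficients (`src/cvbenefit/data/default_risk_model.json`)
and the default constant RR of 0.78 per mmol/L are documented synthetic
stand-ins; substitute transcribed coefficient sets for realism.

## CLI

All subcommands are thin wrappers over library functions
(`cvbenefit --help` for details):

```sh
# full pipeline: simulate -> filter -> estimate -> calibrate -> compare -> report
cvbenefit run --config examples/config.json --seed 42 --out results/run

# or stage by stage
cvbenefit simulate --seed 1 --n 7287 --out cohort.csv
cvbenefit estimate --cohort cohort.csv --out estimates.csv
cvbenefit calibrate --estimates estimates.csv --risk-threshold 0.10 --out calibration.json
cvbenefit compare --estimates estimates.csv --strategies strategies.json \
    --bootstrap 1000 --seed 42 --out results.csv
cvbenefit report --estimates estimates.csv --strategies strategies.json --out report/
```

`run` writes `cohort.csv`, `estimates.csv`, `results.csv` (one row per
strategy, display-rounded), `calibration.json`, concordance/flow/subgroup/
characteristics tables, and a `manifest.json` with the config hash and
output checksums; identical config + seed reproduces byte-identical
outputs.

## Library example

```python
from cvbenefit import (
    GeneratorConfig, TreatmentSpec, StrategyDefinition,
    generate_cohort, apply_inclusion_filters, rescale_weights,
    default_risk_model, predict_untreated_risk, estimate_individuals,
    eligible, calibrate_benefit_threshold, evaluate_strategy,
)

config = GeneratorConfig(n=7287, seed=42)
kept, tally = apply_inclusion_filters(generate_cohort(config))
cohort = rescale_weights(kept, config.target_population)

risk = predict_untreated_risk(cohort, default_risk_model())
est = estimate_individuals(cohort, risk, TreatmentSpec())

high_risk = StrategyDefinition(kind="risk_threshold", threshold=0.10)
mask = eligible(est, high_risk)
target = float((cohort.weight[mask] * est.iarr[mask]).sum())
cal = calibrate_benefit_threshold(est, cohort.weight, target)

print(evaluate_strategy(est, cohort.weight, cal.strategy, bootstrap_reps=1000))
```
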