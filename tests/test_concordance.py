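import numpy as np
import pandas as pd
import pytest

from cvbenefit import (
    compare_characteristics,
    cross_tabulate,
    flow_matrix,
    subgroup_efficiency,
)
from cvbenefit.concordance import ConcordanceResult

from conftest import make_cohort_frame


class TestCrossTabulate:
    def test_printed_style_identity(self):
        # both = either - only_a - only_b; one weighted record per cell (millions)
        result = ConcordanceResult(both=58.9e6 - 9.7e6 - 8.6e6, only_a=9.7e6, only_b=8.6e6, neither=0.0)
        assert result.either == pytest.approx(58.9e6)
        assert round(result.overlap_prop * 100, 1) == 68.9

    def test_weighted_cells(self):
        a = [True, True, False, False]
        b = [True, False, True, False]
        w = [1.0, 2.0, 3.0, 4.0]
        result = cross_tabulate(a, b, w)
        assert result.both == 1.0
        assert result.only_a == 2.0
        assert result.only_b == 3.0
        assert result.neither == 4.0
        assert result.either == 6.0

    def test_identical_indicators(self):
        m = [True, False, True]
        result = cross_tabulate(m, m, [1.0, 1.0, 1.0])
        assert result.overlap_prop == pytest.approx(1.0)

    def test_disjoint_indicators(self):
        result = cross_tabulate([True, False], [False, True], [1.0, 1.0])
        assert result.overlap_prop == 0.0

    def test_empty_either_is_nan(self):
        result = cross_tabulate([False], [False], [5.0])
        assert np.isnan(result.overlap_prop)

    def test_partition_conservation(self):
        rng = np.random.default_rng(8)
        a = rng.random(500) < 0.3
        b = rng.random(500) < 0.4
        w = rng.uniform(1, 100, 500)
        result = cross_tabulate(a, b, w)
        total = result.both + result.only_a + result.only_b + result.neither
        assert total == pytest.approx(w.sum(), rel=1e-9)

    def test_misalignment(self):
        with pytest.raises(ValueError):
            cross_tabulate([True], [True, False], [1.0, 1.0])


class TestFlowMatrix:
    def test_hand_tally(self):
        strata = ["low", "low", "borderline", "high", "high", "intermediate"]
        cats = ["low", "high", "high", "low", "high", "moderate"]
        w = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        table = flow_matrix(strata, cats, w)
        assert table.loc["low", "low"] == 1.0
        assert table.loc["low", "high"] == 2.0
        assert table.loc["borderline", "high"] == 3.0
        assert table.loc["high", "low"] == 4.0
        assert table.loc["high", "high"] == 5.0
        assert table.loc["intermediate", "moderate"] == 6.0

    def test_single_cell(self):
        table = flow_matrix(["high"] * 3, ["high"] * 3, [1.0, 2.0, 3.0])
        assert table.values.sum() == 6.0
        assert table.loc["high", "high"] == 6.0

    def test_margins_conserved(self):
        rng = np.random.default_rng(21)
        strata = rng.choice(["low", "borderline", "intermediate", "high"], 300)
        cats = rng.choice(["low", "moderate", "high"], 300)
        w = rng.uniform(1, 10, 300)
        table = flow_matrix(strata, cats, w)
        for s in np.unique(strata):
            assert table.loc[s].sum() == pytest.approx(w[strata == s].sum(), rel=1e-12)
        for c in np.unique(cats):
            assert table[c].sum() == pytest.approx(w[cats == c].sum(), rel=1e-12)

    def test_unclassified_record_errors(self):
        with pytest.raises(ValueError):
            flow_matrix(["high", None], ["low", "low"], [1.0, 1.0])


class TestSubgroupEfficiency:
    def test_uniform_iarr_nnt(self):
        est = pd.DataFrame({"iarr": [1 / 22] * 4})
        out = subgroup_efficiency(
            [True] * 4, [True] * 4, [True] * 4, est, [10.0] * 4
        )
        assert out.loc["both", "average_nnt"] == pytest.approx(22.0)

    def test_events_sum_to_union(self):
        rng = np.random.default_rng(31)
        n = 100
        r = rng.random(n) < 0.4
        b = rng.random(n) < 0.4
        e = r | b | (rng.random(n) < 0.2)
        est = pd.DataFrame({"iarr": rng.uniform(0.01, 0.1, n)})
        w = rng.uniform(1, 50, n)
        out = subgroup_efficiency(r, b, e, est, w)
        union_events = float(np.sum(w[e] * est["iarr"].to_numpy()[e]))
        assert out["events_averted"].sum() == pytest.approx(union_events, rel=1e-9)

    def test_eight_record_spreadsheet_oracle(self):
        # hand-built masks and weighted sums
        r = [True, True, False, False, False, False, True, False]
        b = [True, False, True, False, True, False, True, False]
        e = [True, True, True, True, True, False, True, True]
        iarr = [0.05, 0.02, 0.06, 0.03, 0.04, 0.01, 0.08, 0.025]
        w = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        est = pd.DataFrame({"iarr": iarr})
        out = subgroup_efficiency(r, b, e, est, w)
        # both: rows 0, 6 -> persons 8, events 1*0.05 + 7*0.08 = 0.61
        assert out.loc["both", "persons"] == 8.0
        assert out.loc["both", "events_averted"] == pytest.approx(0.61)
        assert out.loc["both", "average_nnt"] == pytest.approx(8.0 / 0.61)
        # risk_only: row 1 -> persons 2, events 0.04
        assert out.loc["risk_only", "average_nnt"] == pytest.approx(2.0 / 0.04)
        # benefit_only: rows 2, 4 -> persons 8, events 0.18 + 0.20
        assert out.loc["benefit_only", "average_nnt"] == pytest.approx(8.0 / 0.38)
        # expansion_only: rows 3, 7 -> persons 12, events 0.12 + 0.2
        assert out.loc["expansion_only", "average_nnt"] == pytest.approx(12.0 / 0.32)

    def test_expansion_must_contain_union(self):
        est = pd.DataFrame({"iarr": [0.05]})
        with pytest.raises(ValueError, match="expansion"):
            subgroup_efficiency([True], [False], [False], est, [1.0])

    def test_empty_subgroup_nan_nnt(self):
        est = pd.DataFrame({"iarr": [0.05]})
        out = subgroup_efficiency([True], [True], [True], est, [1.0])
        assert np.isnan(out.loc["risk_only", "average_nnt"])


class TestCompareCharacteristics:
    def test_simple_mean(self):
        records = make_cohort_frame([{"age": 50.0}, {"age": 60.0}, {"age": 70.0}])
        out = compare_characteristics(records, [True, True, False], [False, False, True])
        assert out.loc["group_a", "age_mean"] == pytest.approx(55.0)
        assert out.loc["group_b", "age_mean"] == pytest.approx(70.0)

    def test_weighted_mean(self):
        records = make_cohort_frame(
            [{"age": 0.0, "weight": 1.0}, {"age": 4.0, "weight": 3.0}, {"age": 9.0}]
        )
        out = compare_characteristics(records, [True, True, False], [False, False, True])
        assert out.loc["group_a", "age_mean"] == pytest.approx(3.0)

    def test_weighted_sd_frequency_convention(self):
        records = make_cohort_frame(
            [{"age": 0.0, "weight": 1.0}, {"age": 4.0, "weight": 3.0}, {"age": 9.0}]
        )
        out = compare_characteristics(records, [True, True, False], [False, False, True])
        # freq-weight population SD: sqrt(mean of w*(x-3)^2 / sum w) = sqrt((9 + 3)/4)
        assert out.loc["group_a", "age_sd"] == pytest.approx(np.sqrt(3.0))

    def test_binary_percent(self):
        records = make_cohort_frame(
            [{"smoker": True}, {"smoker": False}, {"smoker": True, "sex": "F"}]
        )
        out = compare_characteristics(records, [True, True, False], [False, False, True])
        assert out.loc["group_a", "smoker_percent"] == pytest.approx(50.0)
        assert out.loc["group_b", "female_percent"] == pytest.approx(100.0)

    def test_directional_ldl_pattern(self):
        # benefit-only records built with higher LDL-C than risk-only records
        benefit_rows = [{"ldl": 4.0, "tc": 6.2, "age": 50.0} for _ in range(5)]
        risk_rows = [{"ldl": 2.4, "tc": 4.8, "age": 65.0} for _ in range(5)]
        records = make_cohort_frame(benefit_rows + risk_rows)
        benefit_mask = [True] * 5 + [False] * 5
        risk_mask = [False] * 5 + [True] * 5
        out = compare_characteristics(
            records, benefit_mask, risk_mask, labels=("benefit_only", "risk_only")
        )
        assert out.loc["benefit_only", "ldl_mean"] > out.loc["risk_only", "ldl_mean"]

    def test_empty_group_errors(self):
        records = make_cohort_frame([{}])
        with pytest.raises(ValueError):
            compare_characteristics(records, [True], [False])
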