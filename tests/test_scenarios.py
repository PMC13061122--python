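"""Scenario levers: overrides, immutability, commutation, paired contrasts."""

import numpy as np
import pytest

import marsim
from marsim.engine import RunConfig, run_cohort
from marsim.metrics import CohortMetrics, net_contribution
from marsim.scenarios import (
    UNSET,
    ScenarioConfig,
    apply_scenario,
    ideal_mar_experiment,
    net_contribution_runs,
    sweep,
)

from conftest import make_params


def _metrics(ccf, by_group=None, mar_per_woman=0.0):
    groups = by_group or {"<20": 0.0, "20-24": 0.0, "25-29": ccf, "30-34": 0.0, "35-39": 0.0, "40+": 0.0}
    return CohortMetrics(
        cohort_size=1000,
        ccf=ccf,
        ccf_by_age_group=groups,
        children_by_mode={},
        deliveries_by_mode={},
        mar_children_per_woman=mar_per_woman,
        mar_share_pct=0.0,
        iui_share_pct=0.0,
        art_share_pct=0.0,
        mean_age_first_birth_years=29.0,
        births_outside_union_pct=0.0,
        multiple_birth_rate_by_mode={},
    )


class TestApplyScenario:
    def test_empty_scenario_is_identity(self, default_params):
        out = apply_scenario(default_params, ScenarioConfig())
        assert out.thresholds == default_params.thresholds
        assert out.treatment.iui == default_params.treatment.iui
        assert out.mar_enabled == default_params.mar_enabled

    def test_baseline_untouched_by_overrides(self, default_params):
        before = default_params.thresholds.max_ivf_icsi_cycles
        apply_scenario(default_params, ScenarioConfig(max_ivf_icsi_cycles=0, uptake_share=0.5))
        assert default_params.thresholds.max_ivf_icsi_cycles == before
        assert default_params.uptake_share is None

    def test_out_of_range_lever_names_the_lever(self, default_params):
        with pytest.raises(ValueError, match="uptake_share"):
            apply_scenario(default_params, ScenarioConfig(uptake_share=1.5))
        with pytest.raises(ValueError, match="added_months_to_diagnosis"):
            apply_scenario(default_params, ScenarioConfig(added_months_to_diagnosis=30))

    def test_diagnosis_lever_is_additive(self, default_params):
        out = apply_scenario(default_params, ScenarioConfig(added_months_to_diagnosis=24))
        assert out.thresholds.diagnosis_min_months_trying == 36

    def test_disjoint_overrides_commute(self, default_params):
        a = apply_scenario(
            apply_scenario(default_params, ScenarioConfig(uptake_share=0.4)),
            ScenarioConfig(max_iui_cycles=2),
        )
        b = apply_scenario(
            apply_scenario(default_params, ScenarioConfig(max_iui_cycles=2)),
            ScenarioConfig(uptake_share=0.4),
        )
        assert a.thresholds == b.thresholds and a.uptake_share == b.uptake_share

    def test_no_age_cap_via_none(self, default_params):
        out = apply_scenario(default_params, ScenarioConfig(max_age_at_mar_years=None))
        assert out.thresholds.max_age_at_mar_years is None
        assert out.thresholds.max_mar_month() > 660


class TestDegenerateLevers:
    def test_uptake_zero_equals_mar_disabled(self):
        params = make_params(fecundability=0.05, ivf_rate=0.3)
        config = RunConfig(cohort_size=2_000, seed=11, params=params)
        a = run_cohort(RunConfig(cohort_size=2_000, seed=11, params=params, scenario=ScenarioConfig(uptake_share=0.0)))
        b = run_cohort(RunConfig(cohort_size=2_000, seed=11, params=params, scenario=ScenarioConfig(mar_enabled=False)))
        assert a.births.equals(b.births)

    def test_zero_cycle_limits_mean_no_mar_births(self):
        params = make_params(fecundability=0.05, ivf_rate=0.5, iui_rate=0.3)
        scenario = ScenarioConfig(max_iui_cycles=0, max_ivf_icsi_cycles=0)
        result = run_cohort(RunConfig(cohort_size=2_000, seed=1, params=params, scenario=scenario))
        assert result.metrics().mar_children_per_woman == 0.0


class TestNetContribution:
    def test_absolute_difference_matches_reported_example(self):
        # headline CCFs with and without treatment: 1.735 vs 1.692
        table = net_contribution(_metrics(1.735), _metrics(1.692))
        total = table[table["group"] == "total"].iloc[0]
        assert total["absolute"] == pytest.approx(0.043, abs=1e-12)
        assert total["relative_pct"] == pytest.approx(100 * 0.043 / 1.692, abs=1e-9)

    def test_identical_runs_give_zero_contribution(self):
        table = net_contribution(_metrics(1.7), _metrics(1.7))
        assert (table["absolute"] == 0).all() and (table["relative_pct"] == 0).all()

    def test_group_absolutes_sum_to_total(self):
        w = _metrics(1.7, {"<20": 0.1, "20-24": 0.3, "25-29": 0.5, "30-34": 0.5, "35-39": 0.2, "40+": 0.1})
        wo = _metrics(1.6, {"<20": 0.1, "20-24": 0.3, "25-29": 0.45, "30-34": 0.45, "35-39": 0.2, "40+": 0.1})
        table = net_contribution(w, wo)
        total = table.loc[table["group"] == "total", "absolute"].iloc[0]
        assert table.loc[table["group"] != "total", "absolute"].sum() == pytest.approx(total)

    def test_zero_denominator_reported_as_undefined(self):
        w = _metrics(1.7, {"<20": 0.1, "20-24": 0.3, "25-29": 0.5, "30-34": 0.5, "35-39": 0.2, "40+": 0.1})
        wo = _metrics(1.6, {"<20": 0.0, "20-24": 0.3, "25-29": 0.5, "30-34": 0.5, "35-39": 0.2, "40+": 0.1})
        table = net_contribution(w, wo)
        rel = table.loc[table["group"] == "<20", "relative_pct"].iloc[0]
        assert np.isnan(rel)


class TestSweeps:
    def test_uptake_lever_weakly_increases_ccf(self, default_params):
        config = RunConfig(cohort_size=5_000, seed=3, params=default_params)
        table = sweep({"uptake_share": [0.0, 1.0]}, config)
        assert table.sort_values("uptake_share")["ccf"].is_monotonic_increasing

    def test_baseline_bitwise_reproducible_after_sweep(self, default_params):
        config = RunConfig(cohort_size=2_000, seed=5, params=default_params)
        before = run_cohort(config).births
        sweep({"max_ivf_icsi_cycles": [0, 3]}, config)
        after = run_cohort(config).births
        assert before.equals(after)

    def test_ideal_experiment_shifts_first_birth_later(self, default_params):
        config = RunConfig(cohort_size=5_000, seed=3, params=default_params)
        table = ideal_mar_experiment([0, 60], config)
        assert table.loc[1, "mean_age_first_birth_years"] > table.loc[0, "mean_age_first_birth_years"]

    def test_net_contribution_runs_are_paired(self, default_params):
        config = RunConfig(cohort_size=3_000, seed=3, params=default_params)
        mw, mo, table = net_contribution_runs(config)
        assert mw.cohort_size == mo.cohort_size == 3_000
        assert mo.mar_children_per_woman == 0.0
        total = table.loc[table["group"] == "total", "absolute"].iloc[0]
        assert total == pytest.approx(mw.ccf - mo.ccf)
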