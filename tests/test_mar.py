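"""The MAR pathway: diagnosis, eligibility, uptake, tracks, cycles, resets."""

import logging

import numpy as np
import pytest

import marsim
from marsim.mar_sim import (
    assign_track,
    attempt_cycles,
    check_diagnosis,
    check_eligibility,
    reset_reimbursement,
    update_mar_state,
)
from marsim.parameters import Thresholds
from marsim.state import (
    MODE_IVF_ICSI,
    MODE_NATURAL,
    TRACK_ART,
    TRACK_EXPECTANT,
    TRACK_IUI,
    TRACK_NONE,
    CohortState,
    EventLog,
)
from marsim.streams import CohortStreams

from conftest import make_params


def build_state(params, n=1, seed=0):
    streams = CohortStreams(seed, 0, np.arange(n))
    return CohortState(np.arange(n), params, streams), streams


class TestDiagnosis:
    def test_minimum_months_trying(self):
        th = Thresholds()
        assert not check_diagnosis(11, th)
        assert check_diagnosis(12, th)

    def test_additive_diagnosis_delay_lever(self):
        th = Thresholds(diagnosis_min_months_trying=36)
        assert not check_diagnosis(35, th)
        assert check_diagnosis(36, th)


class TestEligibility:
    def test_poor_prognosis_below_entry_threshold(self):
        # cum12 = 1 - 0.95**12 ~ 0.46 < 0.58 -> eligible at age 30
        th = Thresholds()
        assert check_eligibility(360, 0.05, th)

    def test_good_prognosis_blocks_entry_below_38(self):
        # cum12 = 1 - 0.92**12 ~ 0.63 >= 0.58 -> not eligible
        th = Thresholds()
        assert not check_eligibility(360, 0.08, th)

    def test_age_38_and_over_admitted_on_diagnosis_alone(self):
        th = Thresholds()
        assert check_eligibility(38 * 12, 0.08, th)

    def test_above_maximum_treatment_age_not_eligible(self):
        th = Thresholds()  # maximum age 43
        assert not check_eligibility(44 * 12, 0.01, th)
        assert check_eligibility(43 * 12 + 11, 0.01, th)

    def test_minimum_age_lever(self):
        th = Thresholds(min_age_at_mar_years=30)
        assert not check_eligibility(29 * 12, 0.01, th)
        assert check_eligibility(30 * 12, 0.01, th)


class TestTrackAssignment:
    def test_gate_splits_iui_and_art(self):
        th = Thresholds()
        assert assign_track(0.005, th) == TRACK_ART  # below the 0.0077 gate
        assert assign_track(0.02, th) == TRACK_IUI

    def test_iui_exhaustion_retests_gate_and_moves_to_art(self):
        # 6 failed IUI cycles with fecundability now below the gate -> ART
        params = make_params(iui_rate=0.0, ivf_rate=0.0)
        state, streams = build_state(params)
        state.baseline_fecundability[0] = 0.006
        state.trying[0] = True
        state.track[0] = TRACK_IUI
        state.iui_cycles_used[0] = 5  # this failure exhausts IUI
        in_union = np.array([True])
        attempt_cycles(state, 360, params, streams, in_union)
        assert state.track[0] == TRACK_ART
        assert state.iui_cycles_used[0] == 6

    def test_iui_exhaustion_above_gate_returns_to_expectant_management(self):
        params = make_params(iui_rate=0.0)
        state, streams = build_state(params)
        state.baseline_fecundability[0] = 0.05
        state.trying[0] = True
        state.track[0] = TRACK_IUI
        state.iui_cycles_used[0] = 5
        attempt_cycles(state, 360, params, streams, np.array([True]))
        assert state.track[0] == TRACK_EXPECTANT


class TestCycles:
    def test_certain_rate_conceives_on_first_cycle(self):
        params = make_params(ivf_rate=1.0)
        state, streams = build_state(params)
        state.trying[0] = True
        state.track[0] = TRACK_ART
        _, conceived, modes = attempt_cycles(state, 360, params, streams, np.array([True]))
        assert conceived.tolist() == [0] and modes.tolist() == [MODE_IVF_ICSI]

    def test_zero_rate_exits_after_three_fresh_cycles(self):
        params = make_params(ivf_rate=0.0, fet_rate=0.0, fet_attempts_per_cycle=0)
        state, streams = build_state(params)
        state.trying[0] = True
        state.track[0] = TRACK_ART
        month = 360
        for _ in range(3):
            state.wait[0] = 0
            attempt_cycles(state, month, params, streams, np.array([True]))
            month += 1
        assert state.ivf_cycles_used[0] == 3
        assert state.track[0] == TRACK_EXPECTANT

    def test_fet_attempt_shares_the_fresh_cycle_slot(self):
        params = make_params(ivf_rate=0.0, fet_rate=0.0, fet_attempts_per_cycle=1)
        state, streams = build_state(params)
        state.trying[0] = True
        state.track[0] = TRACK_ART
        attempt_cycles(state, 360, params, streams, np.array([True]))
        assert state.fet_remaining[0] == 1 and state.ivf_cycles_used[0] == 0
        state.wait[0] = 0
        attempt_cycles(state, 361, params, streams, np.array([True]))
        assert state.fet_remaining[0] == 0 and state.ivf_cycles_used[0] == 1

    def test_cycles_to_conception_geometric(self):
        # constant per-cycle rate, no age decline: success cycle ~ Geometric(r)
        r, n = 0.3, 30_000
        params = make_params(ivf_rate=r, fet_attempts_per_cycle=0, max_ivf_icsi_cycles=6, wait_between_ivf_months=1)
        state, streams = build_state(params, n=n, seed=8)
        state.trying[:] = True
        state.track[:] = TRACK_ART
        success_cycle = np.full(n, -1)
        in_union = np.ones(n, dtype=bool)
        for month in range(360, 372):
            state.wait[:] = 0
            state.trying[:] = success_cycle < 0
            _, conceived, _ = attempt_cycles(state, month, params, streams, in_union)
            newly = conceived[success_cycle[conceived] < 0]
            success_cycle[newly] = state.ivf_cycles_used[newly] + 1
        observed = success_cycle[success_cycle > 0]
        for k in (1, 2, 3):
            prob = r * (1 - r) ** (k - 1)
            prob_cond = prob / (1 - (1 - r) ** 6)
            se = np.sqrt(prob_cond * (1 - prob_cond) / observed.size)
            assert abs((observed == k).mean() - prob_cond) < 4 * se


class TestUptake:
    def test_share_lever_zero_means_nobody_treated(self):
        params = make_params(fecundability=0.03, ivf_rate=0.3)
        params.uptake_share = 0.0
        result = marsim.run_cohort(marsim.RunConfig(cohort_size=500, seed=2, params=params))
        assert not result.women["ever_treated"].any()

    def test_share_lever_one_accepts_every_eligible_woman(self):
        params = make_params(fecundability=0.03, ivf_rate=0.3)
        params.uptake_share = 1.0
        result = marsim.run_cohort(marsim.RunConfig(cohort_size=500, seed=2, params=params))
        decided = result.women[result.women["uptake_decided"]]
        assert len(decided) > 0 and decided["uptake_accepted"].all()

    def test_default_uptake_fraction_matches_distribution_mean(self, default_params):
        result = marsim.run_cohort(marsim.RunConfig(cohort_size=20_000, seed=5, params=default_params))
        decided = result.women[result.women["uptake_decided"]]
        frac = decided["uptake_accepted"].mean()
        p = default_params.uptake.mean()
        se = np.sqrt(p * (1 - p) / len(decided))
        assert abs(frac - p) < 3 * se


class TestReimbursementReset:
    def test_reset_after_mar_outcomes(self):
        params = make_params()
        state, _ = build_state(params)
        state.pregnancy_mode[0] = MODE_IVF_ICSI
        state.ivf_cycles_used[0] = 2
        state.iui_cycles_used[0] = 3
        reset_reimbursement(state, np.array([0]))
        assert state.ivf_cycles_used[0] == 0 and state.iui_cycles_used[0] == 0
        assert state.track[0] == TRACK_NONE

    def test_natural_pregnancy_reset_is_noop_with_warning(self, caplog):
        params = make_params()
        state, _ = build_state(params)
        state.pregnancy_mode[0] = MODE_NATURAL
        state.ivf_cycles_used[0] = 2
        with caplog.at_level(logging.WARNING):
            reset_reimbursement(state, np.array([0]))
        assert state.ivf_cycles_used[0] == 2
        assert any("natural" in r.message for r in caplog.records)


class TestDegenerateEquivalence:
    def test_zero_rates_match_disabled_mar_exactly(self):
        n, seed = 3_000, 9
        zero = make_params(fecundability=0.05, iui_rate=0.0, ivf_rate=0.0, fet_rate=0.0)
        disabled = make_params(fecundability=0.05, mar_enabled=False)
        a = marsim.run_cohort(marsim.RunConfig(cohort_size=n, seed=seed, params=zero))
        b = marsim.run_cohort(marsim.RunConfig(cohort_size=n, seed=seed, params=disabled))
        assert a.births.equals(b.births)
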