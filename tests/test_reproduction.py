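"""Reproductive dynamics: conception timing, losses, plurality, trying rules."""

import numpy as np
import pytest

from marsim.reproduction_sim import (
    decide_trying,
    draw_plurality,
    effective_fecundability,
    monthly_loss_hazard,
    step_reproduction,
)
from marsim.state import MODE_IUI, MODE_IVF_ICSI, MODE_NATURAL, CohortState, EventLog
from marsim.streams import CohortStreams

from conftest import constant_curve, make_params


def build_state(params, n=1, seed=0):
    streams = CohortStreams(seed, 0, np.arange(n))
    return CohortState(np.arange(n), params, streams), streams


def run_months(state, params, streams, first, last, in_union=True, log=None):
    col = np.full(state.n, in_union)
    for month in range(first, last + 1):
        step_reproduction(state, month, params, streams, col, log)


class TestForcedPaths:
    def test_certain_conception_delivers_nine_months_later(self):
        params = make_params(mar_enabled=False)
        state, streams = build_state(params)
        state.baseline_fecundability[:] = 1.0
        run_months(state, params, streams, 180, 195)
        births = state.births_frame()
        assert len(births) == 1
        assert births.loc[0, "age_months"] == 189  # conceived at 180, term at +9
        assert state.parity[0] == 1

    def test_certain_intrauterine_mortality_ends_pregnancy_without_birth(self):
        params = make_params(mortality=1.0, mar_enabled=False)
        state, streams = build_state(params)
        state.pregnant[0] = True
        state.gestation[0] = 3
        state.pregnancy_mode[0] = MODE_NATURAL
        log = EventLog(enabled=True)
        run_months(state, params, streams, 300, 300, log=log)
        assert not state.pregnant[0]
        assert len(state.births_frame()) == 0
        assert (log.to_frame()["event"] == "intrauterine_mortality").any()

    def test_mar_pregnancy_loss_emits_reimbursement_reset(self):
        params = make_params(mortality=1.0)
        state, streams = build_state(params)
        state.pregnant[0] = True
        state.gestation[0] = 4
        state.pregnancy_mode[0] = MODE_IVF_ICSI
        state.ivf_cycles_used[0] = 2
        log = EventLog(enabled=True)
        run_months(state, params, streams, 310, 310, log=log)
        events = log.to_frame()["event"].tolist()
        assert "intrauterine_mortality" in events and "reimbursement_reset" in events
        assert state.ivf_cycles_used[0] == 0


class TestPlurality:
    def test_multinomial_frequencies_match_model(self):
        # P(singleton, twins, triplets) = (1-p, p*k/(k+1), p/(k+1))
        p, k, n = 0.1, 3.0, 50_000
        params = make_params(multiple_p=p, twin_triplet_ratio=k)
        rng = np.random.default_rng(0)
        mode = np.full(n, MODE_IUI)
        plur = draw_plurality(mode, 360, params, rng.random(n), rng.random(n))
        probs = np.array([1 - p, p * k / (k + 1), p / (k + 1)])
        for value, prob in zip((1, 2, 3), probs):
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs((plur == value).mean() - prob) < 3 * se

    def test_mode_specific_rates_use_ratios(self):
        params = make_params(multiple_p=0.02)
        params.multiple_birth.ratios["IVF"] = 10.0
        n = 40_000
        rng = np.random.default_rng(1)
        u1, u2 = rng.random(n), rng.random(n)
        nat = draw_plurality(np.full(n, MODE_NATURAL), 360, params, u1, u2)
        ivf = draw_plurality(np.full(n, MODE_IVF_ICSI), 360, params, u1, u2)
        assert (ivf >= 2).mean() == pytest.approx(10 * (nat >= 2).mean(), rel=0.1)


class TestTryingRules:
    def test_flags_follow_union_parity_and_sterility(self):
        params = make_params(intended_family_size={2: 1.0})
        state, _ = build_state(params, n=4)
        state.parity[:] = [0, 2, 0, 0]
        state.sterility_month[2] = 200  # sterile by the test month
        in_union = np.array([True, True, True, False])
        decide_trying(state, 300, in_union)
        assert state.trying.tolist() == [True, False, False, False]
        assert state.contracepting.tolist() == [False, True, False, False]

    def test_pregnant_women_neither_try_nor_contracept(self):
        params = make_params()
        state, _ = build_state(params, n=1)
        state.pregnant[0] = True
        decide_trying(state, 300, np.array([True]))
        assert not state.trying[0] and not state.contracepting[0]


class TestEffectiveFecundability:
    def test_sterility_zeroes_fecundability(self):
        params = make_params()
        state, _ = build_state(params)
        state.sterility_month[0] = 240
        assert effective_fecundability(state, 300)[0] == 0.0

    def test_decline_multiplier_scales_baseline(self):
        params = make_params(decline=constant_curve(0.4))
        state, _ = build_state(params)
        state.baseline_fecundability[0] = 0.2
        assert effective_fecundability(state, 300)[0] == pytest.approx(0.08)


class TestWaitingTimes:
    def test_conception_waiting_time_is_geometric(self):
        # constant fecundability, MAR off: months to conception ~ Geometric(f)
        f, n = 0.2, 20_000
        params = make_params(mar_enabled=False, intended_family_size={1: 1.0})
        state, streams = build_state(params, n=n, seed=13)
        state.baseline_fecundability[:] = f
        conception_month = np.full(n, -1)
        col = np.ones(n, dtype=bool)
        for month in range(180, 240):
            before = state.pregnant.copy()
            step_reproduction(state, month, params, streams, col)
            new = state.pregnant & ~before
            conception_month[(conception_month < 0) & new] = month
        waits = conception_month[conception_month > 0] - 180 + 1  # trials to success
        ks = _ks_vs_geometric(waits, f)
        assert ks < 1.63 / np.sqrt(waits.size)  # asymptotic 1% critical value

    def test_contraception_failure_rate_drives_unintended_conceptions(self):
        rate, n = 0.05, 20_000
        params = make_params(
            contraception_failure=rate, abortion_probability=0.0, intended_family_size={0: 1.0}, mar_enabled=False
        )
        state, streams = build_state(params, n=n, seed=21)
        col = np.ones(n, dtype=bool)
        step_reproduction(state, 300, params, streams, col)
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(state.pregnant.mean() - rate) < 3 * se


def _ks_vs_geometric(waits, f):
    kmax = int(waits.max())
    grid = np.arange(1, kmax + 1)
    emp = np.searchsorted(np.sort(waits), grid, side="right") / waits.size
    theo = 1.0 - (1.0 - f) ** grid
    theo /= theo[-1]  # censor at the observation horizon
    return np.abs(emp - theo).max()


def test_monthly_loss_hazard_cumulates_to_curve_value():
    loss = 0.3
    h = monthly_loss_hazard(loss)
    assert 1 - (1 - h) ** 9 == pytest.approx(loss, abs=1e-12)
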