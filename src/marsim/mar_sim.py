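"""The medically-assisted-reproduction (MAR) treatment pathway.

A couple trying to conceive is diagnosed infertile after a minimum number of
unsuccessful months (12 by default).  Entry into treatment requires the
woman's age to lie inside the reimbursement window and, below age 38, a poor
natural prognosis: a cumulative conception probability over the next 12
months below 58% (a leniency-adjusted Hunault-style criterion).  Uptake is a
one-shot Bernoulli decision with the woman's bootstrapped uptake
probability; refusal is permanent.

Treatment starts on the IUI track unless effective fecundability is below
the ART gate (0.0077/month), in which case the woman moves directly to
IVF/ICSI.  Up to six IUI cycles are reimbursed; after exhausting them the
gate is re-tested (age has lowered fecundability by then) and the woman
either moves to ART or returns to expectant management.  Up to three fresh
IVF/ICSI cycles are reimbursed, each followed by a configurable number of
frozen-embryo-transfer (FET) attempts that share the cycle's reimbursement
slot.  Cycle counters reset to their maxima when a MAR pregnancy ends in a
live birth or intrauterine mortality.
"""

from __future__ import annotations

import logging

import numpy as np

from .parameters import ParameterSet, Thresholds, cumulative_conception_probability
from .state import (
    MODE_FET,
    MODE_IUI,
    MODE_IVF_ICSI,
    MODE_NATURAL,
    TRACK_ART,
    TRACK_EXPECTANT,
    TRACK_IUI,
    TRACK_NONE,
    CohortState,
    EventLog,
)
from .streams import Channel, CohortStreams

log_ = logging.getLogger(__name__)

__all__ = [
    "check_diagnosis",
    "check_eligibility",
    "assign_track",
    "update_mar_state",
    "attempt_cycles",
    "reset_reimbursement",
]


def check_diagnosis(months_trying, thresholds: Thresholds):
    """Infertility diagnosis after the minimum number of months trying."""
    return np.asarray(months_trying) >= thresholds.diagnosis_min_months_trying


def check_eligibility(age_months, effective_fecundability, thresholds: Thresholds):
    """Treatment-entry eligibility for a diagnosed woman.

    Requires age inside [min_age_at_mar, max_age_at_mar].  Below the
    prognosis-check age limit (38), additionally requires a predicted
    12-month natural conception probability under the entry threshold (58%);
    at or above that age, diagnosis alone suffices.
    """
    age = np.asarray(age_months)
    in_window = (age >= thresholds.min_mar_month()) & (age <= thresholds.max_mar_month())
    cum12 = cumulative_conception_probability(effective_fecundability, 12)
    poor_prognosis = np.asarray(cum12) < thresholds.entry_cum12_threshold
    no_check_needed = age >= thresholds.entry_check_max_month()
    return in_window & (no_check_needed | poor_prognosis)


def assign_track(effective_fecundability, thresholds: Thresholds):
    """Initial track: ART below the fecundability gate, IUI otherwise."""
    below_gate = np.asarray(effective_fecundability) < thresholds.art_fecundability_gate
    return np.where(below_gate, TRACK_ART, TRACK_IUI).astype(np.int8)


def reset_reimbursement(state: CohortState, idx: np.ndarray, log: EventLog = None, month: int = -1) -> None:
    """Reset cycle counters after a MAR pregnancy ends (birth or loss).

    Calling it for a naturally conceived pregnancy is a no-op with a warning
    (the rule only covers MAR pregnancies).
    """
    idx = np.atleast_1d(np.asarray(idx, dtype=np.int64))
    if idx.size == 0:
        return
    natural = state.pregnancy_mode[idx] == MODE_NATURAL
    if np.any(natural):
        log_.warning("reimbursement reset requested after a natural pregnancy; ignored")
        idx = idx[~natural]
        if idx.size == 0:
            return
    state.iui_cycles_used[idx] = 0
    state.ivf_cycles_used[idx] = 0
    state.fet_remaining[idx] = 0
    state.track[idx] = TRACK_NONE
    state.wait[idx] = 0
    if log is not None:
        log.record(month, state.woman_id[idx], "reimbursement_reset")


def update_mar_state(
    state: CohortState,
    month: int,
    params: ParameterSet,
    streams: CohortStreams,
    in_union: np.ndarray,
    log: EventLog = None,
) -> None:
    """Monthly pathway bookkeeping: diagnosis, entry, uptake, tracks, waits."""
    if not params.mar_enabled:
        return
    log = log or EventLog(enabled=False)
    th = params.thresholds

    # waiting clocks tick first; newly assigned waits start next month
    on_track = (state.track == TRACK_IUI) | (state.track == TRACK_ART)
    ticking = on_track & (state.wait > 0)
    state.wait[ticking] -= 1

    # diagnosis
    newly = state.trying & ~state.diagnosed & check_diagnosis(state.months_trying, th)
    if np.any(newly):
        state.diagnosed[newly] = True
        state.diagnosis_month[newly] = month
        log.record(month, state.woman_id[newly], "diagnosis")

    # entry check + one-shot uptake decision (re-checked monthly until the
    # woman first becomes eligible; the decision itself is permanent)
    from .reproduction_sim import effective_fecundability  # local import, no cycle at module load

    cand = np.flatnonzero(state.diagnosed & state.trying & ~state.uptake_decided)
    if cand.size:
        eff = effective_fecundability(state, month, cand)
        eligible = cand[check_eligibility(month, eff, th)]
        if eligible.size:
            p = params.uptake_share if params.uptake_share is not None else state.uptake_probability[eligible]
            u = streams.uniform(month, Channel.UPTAKE_DECISION, eligible)
            accept = u < p
            state.uptake_decided[eligible] = True
            state.uptake_accepted[eligible] = accept
            log.record(month, state.woman_id[eligible], "uptake_decision", accept)

    # track (re-)assignment: on acceptance, and again after each
    # reimbursement reset; respects the age window and remaining cycles
    ready = np.flatnonzero(
        state.uptake_accepted
        & state.trying
        & (state.track == TRACK_NONE)
        & in_union
        & (month >= th.min_mar_month())
        & (month <= th.max_mar_month())
    )
    if ready.size:
        eff = effective_fecundability(state, month, ready)
        want = assign_track(eff, th)
        iui_ok = state.iui_cycles_used[ready] < th.max_iui_cycles
        ivf_ok = state.ivf_cycles_used[ready] < th.max_ivf_icsi_cycles
        # above-gate women with no IUI cycles available are treated as having
        # exhausted IUI: the gate re-test fails by construction, so they stay
        # on expectant management rather than falling through to ART
        to_art = (want == TRACK_ART) & ivf_ok
        to_iui = (want == TRACK_IUI) & iui_ok
        none_left = ~(to_art | to_iui)
        art_idx = ready[to_art]
        iui_idx = ready[to_iui]
        state.track[art_idx] = TRACK_ART
        state.wait[art_idx] = th.wait_first_ivf_months
        state.track[iui_idx] = TRACK_IUI
        state.wait[iui_idx] = th.wait_first_iui_months
        state.track[ready[none_left]] = TRACK_EXPECTANT
        log.record(month, state.woman_id[art_idx], "track_art")
        log.record(month, state.woman_id[iui_idx], "track_iui")


def attempt_cycles(
    state: CohortState,
    month: int,
    params: ParameterSet,
    streams: CohortStreams,
    in_union: np.ndarray,
    log: EventLog = None,
):
    """Run this month's treatment cycles.

    Returns ``(attempted_mask, conceived_idx, conceived_modes)``.  A cycle
    runs only for women on an active track with a zero waiting clock, inside
    a union and the reimbursement age window, with cycles remaining.
    """
    log = log or EventLog(enabled=False)
    th = params.thresholds
    n = state.n
    attempted = np.zeros(n, dtype=bool)
    empty = np.array([], dtype=np.int64)
    if not params.mar_enabled:
        return attempted, empty, empty

    active = (
        state.trying
        & ~state.pregnant
        & ((state.track == TRACK_IUI) | (state.track == TRACK_ART))
        & (state.wait == 0)
        & in_union
        & (month >= th.min_mar_month())
        & (month <= th.max_mar_month())
    )
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return attempted, empty, empty
    attempted[idx] = True
    state.ever_treated[idx] = True

    is_iui = state.track[idx] == TRACK_IUI
    is_fet = (state.track[idx] == TRACK_ART) & (state.fet_remaining[idx] > 0)
    is_fresh = (state.track[idx] == TRACK_ART) & ~is_fet

    # state-machine invariant: an active track implies cycles remaining
    assert np.all(state.iui_cycles_used[idx[is_iui]] < th.max_iui_cycles), "IUI attempt with no cycles left"
    assert np.all(state.ivf_cycles_used[idx[is_fresh]] < th.max_ivf_icsi_cycles), "IVF attempt with no cycles left"

    rate_iui = params.treatment.iui.at(month)
    rate_ivf = params.treatment.ivf.at(month)
    rate_fet = params.treatment.fet.at(month)
    rate = np.where(is_iui, rate_iui, np.where(is_fet, rate_fet, rate_ivf))

    u = streams.uniform(month, Channel.MAR_CYCLE, idx)
    success = u < rate
    mode = np.where(is_iui, MODE_IUI, np.where(is_fet, MODE_FET, MODE_IVF_ICSI)).astype(np.int8)
    log.record(month, state.woman_id[idx], "mar_cycle", success.astype(float))

    # -- failure accounting ---------------------------------------------
    fail = ~success
    # IUI failures
    f_iui = idx[fail & is_iui]
    if f_iui.size:
        state.iui_cycles_used[f_iui] += 1
        exhausted = state.iui_cycles_used[f_iui] >= th.max_iui_cycles
        state.wait[f_iui[~exhausted]] = th.wait_between_iui_months
        exh = f_iui[exhausted]
        if exh.size:
            from .reproduction_sim import effective_fecundability

            eff = effective_fecundability(state, month, exh)
            to_art = (eff < th.art_fecundability_gate) & (state.ivf_cycles_used[exh] < th.max_ivf_icsi_cycles)
            state.track[exh[to_art]] = TRACK_ART
            state.wait[exh[to_art]] = th.wait_first_ivf_months
            state.track[exh[~to_art]] = TRACK_EXPECTANT
            log.record(month, state.woman_id[exh[to_art]], "track_art")
            log.record(month, state.woman_id[exh[~to_art]], "track_expectant")

    # fresh IVF/ICSI failures: FET attempts share the cycle slot
    f_fresh = idx[fail & is_fresh]
    closing = empty
    if f_fresh.size:
        if th.fet_attempts_per_cycle > 0:
            state.fet_remaining[f_fresh] = th.fet_attempts_per_cycle
            state.wait[f_fresh] = th.wait_between_ivf_months
        else:
            closing = f_fresh

    # FET failures
    f_fet = idx[fail & is_fet]
    if f_fet.size:
        state.fet_remaining[f_fet] -= 1
        still = state.fet_remaining[f_fet] > 0
        state.wait[f_fet[still]] = th.wait_between_ivf_months
        closing = np.concatenate([closing, f_fet[~still]])

    if closing.size:  # a fresh cycle (and its FETs) is spent
        state.ivf_cycles_used[closing] += 1
        done = state.ivf_cycles_used[closing] >= th.max_ivf_icsi_cycles
        state.wait[closing[~done]] = th.wait_between_ivf_months
        state.track[closing[done]] = TRACK_EXPECTANT
        log.record(month, state.woman_id[closing[done]], "track_expectant")

    return attempted, idx[success], mode[success]
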