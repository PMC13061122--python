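"""Monthly reproductive dynamics: trying, conception, pregnancy, birth.

Within a month the event order is fixed (union transition happens first, in
the union simulation): decide trying/contracepting -> MAR state update ->
conception attempts (treatment cycle or natural) -> contraceptive failure ->
pregnancy progression or loss -> delivery.  A pregnancy lasts 9 months of
gestation; the age-specific per-pregnancy loss probability is converted to a
constant monthly hazard over gestation so its cumulative risk matches the
curve.  Conception never occurs outside a coresidential union.
"""

from __future__ import annotations

import numpy as np

from . import mar_sim
from .parameters import ParameterSet
from .state import (
    GESTATION_MONTHS,
    MODE_FET,
    MODE_IUI,
    MODE_IVF_ICSI,
    MODE_NATURAL,
    CohortState,
    EventLog,
)
from .streams import Channel, CohortStreams

__all__ = [
    "effective_fecundability",
    "decide_trying",
    "monthly_loss_hazard",
    "draw_plurality",
    "step_reproduction",
]


def effective_fecundability(state: CohortState, month: int, index=None) -> np.ndarray:
    """Monthly natural conception probability at the current age.

    Baseline fecundability times the age-decline multiplier; zero from the
    month of sterility onset.
    """
    base = state.baseline_fecundability if index is None else state.baseline_fecundability[index]
    onset = state.sterility_month if index is None else state.sterility_month[index]
    mult = state.params.fecundability.decline.at(month)
    return np.where(onset <= month, 0.0, base * mult)


def decide_trying(state: CohortState, month: int, in_union: np.ndarray) -> None:
    """Set the trying / contracepting flags for this month.

    A woman tries iff she is in a coresidential union, below her intended
    family size, not pregnant, not post-partum, and not sterile; she
    contracepts iff in union, susceptible, and at or above her intended size.
    """
    susceptible = ~state.pregnant & (state.postpartum == 0)
    below_intended = state.parity < state.intended_family_size
    sterile = state.sterile(month)
    state.trying = in_union & susceptible & below_intended & ~sterile
    state.contracepting = in_union & susceptible & ~below_intended


def monthly_loss_hazard(per_pregnancy_loss: float) -> float:
    """Constant monthly hazard whose 9-month cumulative risk equals the curve."""
    return 1.0 - (1.0 - per_pregnancy_loss) ** (1.0 / GESTATION_MONTHS)


def draw_plurality(mode: np.ndarray, month: int, params: ParameterSet, u_multiple: np.ndarray, u_twin: np.ndarray) -> np.ndarray:
    """Plurality (1/2/3) per delivery from the mode-specific multiple-birth model."""
    mb = params.multiple_birth
    p_nat = mb.natural.at(month)
    p_by_mode = np.array(
        [
            p_nat,
            min(1.0, p_nat * mb.ratios["IUI"]),
            min(1.0, p_nat * mb.ratios["IVF"]),
            min(1.0, p_nat * mb.ratios["FET"]),
        ]
    )
    multiple = u_multiple < p_by_mode[mode]
    twins = u_twin < mb.twin_probability()
    return np.where(multiple, np.where(twins, 2, 3), 1).astype(np.int8)


def _start_pregnancies(state: CohortState, idx: np.ndarray, mode, month: int, log: EventLog) -> None:
    state.conceived_this_month[idx] = True
    state.pregnant[idx] = True
    state.gestation[idx] = 0
    state.pregnancy_mode[idx] = mode
    state.months_trying[idx] = 0
    state.trying[idx] = False
    state.contracepting[idx] = False
    log.record(month, state.woman_id[idx], "conception", np.broadcast_to(mode, idx.shape))


def step_reproduction(
    state: CohortState,
    month: int,
    params: ParameterSet,
    streams: CohortStreams,
    in_union: np.ndarray,
    log: EventLog = None,
) -> None:
    """Advance the whole cohort one month of reproductive life."""
    log = log or EventLog(enabled=False)
    state.conceived_this_month[:] = False

    # 1. who is trying / contracepting this month
    decide_trying(state, month, in_union)

    # 2. MAR pathway bookkeeping (diagnosis, eligibility, uptake, tracks, waits)
    mar_sim.update_mar_state(state, month, params, streams, in_union, log)

    # 3. conception attempts.  A treatment cycle runs in parallel with the
    #    natural channel: the cycle succeeds with its per-cycle rate, and a
    #    woman whose cycle failed (or who is waiting, refused, or untreated)
    #    still conceives naturally with her effective fecundability that
    #    month.  The natural draws are keyed per (woman, month), so a run
    #    with zero treatment rates reproduces a MAR-disabled run exactly.
    _, mar_idx, mar_modes = mar_sim.attempt_cycles(state, month, params, streams, in_union, log)
    _start_pregnancies(state, mar_idx, mar_modes, month, log)

    nat_idx = np.flatnonzero(state.trying)
    if nat_idx.size:
        eff = effective_fecundability(state, month, nat_idx)
        u = streams.uniform(month, Channel.NATURAL_CONCEPTION, nat_idx)
        conceived = nat_idx[u < eff]
        _start_pregnancies(state, conceived, MODE_NATURAL, month, log)

    # 4. contraceptive failure -> unintended conception, possibly aborted
    con_idx = np.flatnonzero(state.contracepting & ~state.sterile(month))
    if con_idx.size:
        u = streams.uniform(month, Channel.CONTRACEPTION, con_idx)
        failed = con_idx[u < params.contraception.monthly_failure]
        if failed.size:
            u2 = streams.uniform(month, Channel.ABORTION, failed)
            aborted = failed[u2 < params.contraception.abortion_probability]
            carried = failed[u2 >= params.contraception.abortion_probability]
            log.record(month, state.woman_id[aborted], "abortion")
            _start_pregnancies(state, carried, MODE_NATURAL, month, log)

    # 5. pregnancy progression for pregnancies begun before this month
    ongoing = np.flatnonzero(state.pregnant & ~state.conceived_this_month)
    if ongoing.size:
        loss_p = monthly_loss_hazard(params.intrauterine_mortality.at(month))
        u = streams.uniform(month, Channel.PREGNANCY_LOSS, ongoing)
        lost = ongoing[u < loss_p]
        if lost.size:
            log.record(month, state.woman_id[lost], "intrauterine_mortality", state.pregnancy_mode[lost])
            mar_lost = lost[state.pregnancy_mode[lost] != MODE_NATURAL]
            mar_sim.reset_reimbursement(state, mar_lost, log=log, month=month)
            state.pregnant[lost] = False
            state.gestation[lost] = 0
            state.pregnancy_mode[lost] = MODE_NATURAL
        alive = ongoing[u >= loss_p]
        state.gestation[alive] += 1
        due = alive[state.gestation[alive] >= GESTATION_MONTHS]
        if due.size:
            u1 = streams.uniform(month, Channel.PLURALITY, due)
            u2 = streams.uniform(month, Channel.TWIN_TRIPLET, due)
            mode = state.pregnancy_mode[due]
            plurality = draw_plurality(mode, month, params, u1, u2)
            state.record_births(due, month, plurality, mode, in_union[due])
            log.record(month, state.woman_id[due], "birth", plurality)
            state.parity[due] += plurality
            mar_born = due[mode != MODE_NATURAL]
            mar_sim.reset_reimbursement(state, mar_born, log=log, month=month)
            state.pregnant[due] = False
            state.gestation[due] = 0
            state.pregnancy_mode[due] = MODE_NATURAL
            state.postpartum[due] = params.thresholds.postpartum_months

    # 6. month-end counters
    still_trying = state.trying & ~state.pregnant
    state.months_trying[still_trying] += 1
    pp = state.postpartum > 0
    state.postpartum[pp] -= 1
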