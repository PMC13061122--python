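"""Monthly coresidential-union trajectories.

Union histories are simulated first, before the reproductive simulation, as
discrete-time Bernoulli transitions: a single woman forms a union with the
age- and education-specific formation hazard, a coresiding woman dissolves it
with the dissolution hazard.  The postponement lever delays the formation
schedule: with a shift of ``s`` months the hazard at age ``a`` is read from
``a - s`` (zero before the schedule starts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import AGE_MAX_MONTHS, AGE_MIN_MONTHS
from .parameters import EDUCATION_LEVELS, UnionHazards
from .streams import Channel, CohortStreams, WomanStream

NEVER = 10**6

__all__ = ["UnionTrajectory", "simulate_union_cohort", "simulate_union_trajectory", "mean_age_at_first_union"]


@dataclass
class UnionTrajectory:
    """Per-month union status for a cohort (rows = women, cols = months)."""

    months: np.ndarray  # age months, 180..660
    in_union: np.ndarray  # (n, T) bool
    union_index: np.ndarray  # (n, T) int16, 0 before the first union

    @property
    def n(self) -> int:
        return self.in_union.shape[0]

    def first_union_month(self) -> np.ndarray:
        """Age month of first coresidence per woman (NEVER if none)."""
        any_union = self.in_union.any(axis=1)
        first = np.argmax(self.in_union, axis=1)
        return np.where(any_union, self.months[0] + first, NEVER)

    def column(self, month: int) -> np.ndarray:
        return self.in_union[:, month - int(self.months[0])]


def _hazard_matrix(hazards: dict, education: np.ndarray, months: np.ndarray, shift: int = 0) -> np.ndarray:
    """(levels, T) hazard lookup table, with the formation-shift applied."""
    table = np.zeros((len(EDUCATION_LEVELS), months.size))
    for k, edu in enumerate(EDUCATION_LEVELS):
        curve = hazards[edu]
        src = months - shift
        ok = (src >= curve.start) & (src <= curve.stop)
        table[k, ok] = curve.lookup(src[ok])
    return table


def simulate_union_cohort(
    education: np.ndarray,
    hazards: UnionHazards,
    streams: CohortStreams,
    age_shift_months: int = 0,
    refractory_months: int = 0,
) -> UnionTrajectory:
    """Simulate monthly union trajectories for a cohort.

    ``age_shift_months`` delays the formation hazard schedule (postponement
    lever); ``refractory_months`` blocks re-partnering for that many months
    after a dissolution.
    """
    if age_shift_months < 0:
        raise ValueError("age_shift_months must be >= 0")
    months = np.arange(AGE_MIN_MONTHS, AGE_MAX_MONTHS + 1)
    n, T = education.size, months.size
    form = _hazard_matrix(hazards.formation, education, months, shift=age_shift_months)
    diss = _hazard_matrix(hazards.dissolution, education, months, shift=0)

    in_union = np.zeros((n, T), dtype=bool)
    union_index = np.zeros((n, T), dtype=np.int16)
    status = np.zeros(n, dtype=bool)
    uidx = np.zeros(n, dtype=np.int16)
    since_dissolution = np.full(n, np.iinfo(np.int32).max, dtype=np.int64)

    edu = education.astype(np.int64)
    for t, m in enumerate(months):
        u = streams.uniform(int(m), Channel.UNION)
        can_form = ~status & (since_dissolution >= refractory_months)
        forms = can_form & (u < form[edu, t])
        dissolves = status & (u < diss[edu, t])
        status[forms] = True
        uidx[forms] += 1
        status[dissolves] = False
        since_dissolution[dissolves] = 0
        since_dissolution[~status] += 1
        in_union[:, t] = status
        union_index[:, t] = uidx
    return UnionTrajectory(months=months, in_union=in_union, union_index=union_index)


def simulate_union_trajectory(
    education: str,
    hazards: UnionHazards,
    age_shift_months: int = 0,
    stream: WomanStream = None,
    refractory_months: int = 0,
) -> UnionTrajectory:
    """Single-woman convenience wrapper around :func:`simulate_union_cohort`."""
    if stream is None:
        stream = WomanStream(0, 0, 0)
    edu_code = np.array([EDUCATION_LEVELS.index(education)], dtype=np.int8)
    return simulate_union_cohort(
        edu_code, hazards, stream, age_shift_months=age_shift_months, refractory_months=refractory_months
    )


def mean_age_at_first_union(trajectories: UnionTrajectory) -> float:
    """Mean age in years at first coresidence among women ever in a union."""
    first = trajectories.first_union_month()
    ever = first < NEVER
    if not np.any(ever):
        raise ValueError("no woman in the cohort ever formed a union")
    return float(first[ever].mean() / 12.0)
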