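"""Per-woman simulation state, birth records, and the event log.

The cohort is stored as a struct-of-arrays (:class:`CohortState`) so the
monthly update kernels can be vectorised; :class:`Woman` is a readable
snapshot of one woman's row for inspection and single-woman tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .parameters import EDUCATION_LEVELS, NEVER, ParameterSet
from .streams import Channel, CohortStreams

# conception-mode codes
MODE_NATURAL = 0
MODE_IUI = 1
MODE_IVF_ICSI = 2
MODE_FET = 3
MODE_NAMES = {MODE_NATURAL: "natural", MODE_IUI: "IUI", MODE_IVF_ICSI: "IVF-ICSI", MODE_FET: "FET"}
MAR_MODES = (MODE_IUI, MODE_IVF_ICSI, MODE_FET)

# MAR track codes
TRACK_NONE = 0
TRACK_IUI = 1
TRACK_ART = 2
TRACK_EXPECTANT = 3  # exhausted / gate-failed: back to expectant management
TRACK_NAMES = {TRACK_NONE: "none", TRACK_IUI: "IUI", TRACK_ART: "ART", TRACK_EXPECTANT: "expectant"}

GESTATION_MONTHS = 9

__all__ = [
    "MODE_NATURAL",
    "MODE_IUI",
    "MODE_IVF_ICSI",
    "MODE_FET",
    "MODE_NAMES",
    "MAR_MODES",
    "TRACK_NONE",
    "TRACK_IUI",
    "TRACK_ART",
    "TRACK_EXPECTANT",
    "GESTATION_MONTHS",
    "BirthRecord",
    "Woman",
    "CohortState",
    "EventLog",
]


@dataclass(frozen=True)
class BirthRecord:
    """One live delivery: maternal age, plurality, conception mode, union flag."""

    woman_id: int
    age_months: int
    plurality: int  # 1 singleton, 2 twins, 3 triplets
    mode: int  # conception-mode code
    in_union: bool

    @property
    def mode_name(self) -> str:
        return MODE_NAMES[self.mode]


class EventLog:
    """Append-only log of simulation events (optional, for audit and tests)."""

    COLUMNS = ("month", "woman_id", "event", "value")

    def __init__(self, enabled: bool = False):
        self.enabled = enabled
        self._rows: list = []

    def record(self, month: int, woman_ids, event: str, values=None) -> None:
        if not self.enabled:
            return
        woman_ids = np.atleast_1d(woman_ids)
        if woman_ids.size == 0:
            return
        values = np.zeros(woman_ids.size) if values is None else np.broadcast_to(values, woman_ids.shape)
        for w, v in zip(woman_ids, values):
            self._rows.append((month, int(w), event, float(v)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=self.COLUMNS)


class CohortState:
    """Struct-of-arrays state for ``n`` women."""

    def __init__(self, woman_ids: np.ndarray, params: ParameterSet, streams: CohortStreams):
        n = woman_ids.size
        self.n = n
        self.woman_id = np.asarray(woman_ids, dtype=np.int64)
        self.params = params

        # fixed attributes, drawn from keyed attribute channels (month 0)
        edu_probs = np.array([params.education_distribution[e] for e in EDUCATION_LEVELS])
        u = streams.uniform(0, Channel.ATTR_EDUCATION)
        self.education = np.searchsorted(np.cumsum(edu_probs), u, side="right").astype(np.int8)
        self.education = np.minimum(self.education, len(EDUCATION_LEVELS) - 1)

        ifs_items = sorted(params.intended_family_size_distribution.items())
        ifs_vals = np.array([k for k, _ in ifs_items])
        ifs_cdf = np.cumsum([p for _, p in ifs_items])
        u = streams.uniform(0, Channel.ATTR_FAMILY_SIZE)
        self.intended_family_size = ifs_vals[
            np.minimum(np.searchsorted(ifs_cdf, u, side="right"), len(ifs_vals) - 1)
        ].astype(np.int8)

        u = streams.uniform(0, Channel.ATTR_FECUNDABILITY)
        self.baseline_fecundability = params.fecundability.sample_baseline(u)

        u = streams.uniform(0, Channel.ATTR_STERILITY)
        self.sterility_month = params.sterility.sample_onset(u)

        u = streams.uniform(0, Channel.ATTR_UPTAKE_INDEX)
        self.uptake_probability = params.uptake.assign(u)

        # evolving reproductive state
        self.parity = np.zeros(n, dtype=np.int16)
        self.pregnant = np.zeros(n, dtype=bool)
        self.gestation = np.zeros(n, dtype=np.int8)
        self.pregnancy_mode = np.full(n, MODE_NATURAL, dtype=np.int8)
        self.trying = np.zeros(n, dtype=bool)
        self.contracepting = np.zeros(n, dtype=bool)
        self.months_trying = np.zeros(n, dtype=np.int16)
        self.postpartum = np.zeros(n, dtype=np.int8)
        self.conceived_this_month = np.zeros(n, dtype=bool)

        # MAR state
        self.diagnosed = np.zeros(n, dtype=bool)
        self.diagnosis_month = np.full(n, -1, dtype=np.int32)
        self.uptake_decided = np.zeros(n, dtype=bool)
        self.uptake_accepted = np.zeros(n, dtype=bool)
        self.track = np.zeros(n, dtype=np.int8)
        self.iui_cycles_used = np.zeros(n, dtype=np.int8)
        self.ivf_cycles_used = np.zeros(n, dtype=np.int8)
        self.fet_remaining = np.zeros(n, dtype=np.int8)
        self.wait = np.zeros(n, dtype=np.int16)
        self.ever_treated = np.zeros(n, dtype=bool)

        # birth accumulation (column lists, concatenated at the end)
        self._birth_cols: dict = {k: [] for k in ("woman_id", "age_months", "plurality", "mode", "in_union")}
        self.first_birth_month = np.full(n, -1, dtype=np.int32)

    # -- helpers ---------------------------------------------------------
    def sterile(self, month: int) -> np.ndarray:
        return self.sterility_month <= month

    def record_births(self, idx: np.ndarray, month: int, plurality: np.ndarray, mode: np.ndarray, in_union: np.ndarray):
        self._birth_cols["woman_id"].append(self.woman_id[idx])
        self._birth_cols["age_months"].append(np.full(idx.size, month, dtype=np.int32))
        self._birth_cols["plurality"].append(plurality.astype(np.int8))
        self._birth_cols["mode"].append(mode.astype(np.int8))
        self._birth_cols["in_union"].append(in_union.astype(bool))
        first = self.first_birth_month[idx] < 0
        self.first_birth_month[idx[first]] = month

    def births_frame(self) -> pd.DataFrame:
        cols = {
            k: (np.concatenate(v) if v else np.array([], dtype=np.int64))
            for k, v in self._birth_cols.items()
        }
        frame = pd.DataFrame(cols)
        frame["mode_name"] = frame["mode"].map(MODE_NAMES) if len(frame) else frame.get("mode")
        return frame

    def women_frame(self, ever_union: Optional[np.ndarray] = None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "woman_id": self.woman_id,
                "education": [EDUCATION_LEVELS[e] for e in self.education],
                "intended_family_size": self.intended_family_size,
                "baseline_fecundability": self.baseline_fecundability,
                "sterility_month": self.sterility_month,
                "uptake_probability": self.uptake_probability,
                "parity": self.parity,
                "diagnosed": self.diagnosed,
                "diagnosis_month": self.diagnosis_month,
                "uptake_decided": self.uptake_decided,
                "uptake_accepted": self.uptake_accepted,
                "ever_treated": self.ever_treated,
                "first_birth_month": self.first_birth_month,
            }
        )
        if ever_union is not None:
            frame["ever_union"] = ever_union
        return frame

    def woman(self, i: int) -> "Woman":
        return Woman(
            id=int(self.woman_id[i]),
            education=EDUCATION_LEVELS[self.education[i]],
            intended_family_size=int(self.intended_family_size[i]),
            baseline_fecundability=float(self.baseline_fecundability[i]),
            sterility_month=int(self.sterility_month[i]),
            uptake_probability=float(self.uptake_probability[i]),
            parity=int(self.parity[i]),
            pregnant=bool(self.pregnant[i]),
            gestation=int(self.gestation[i]),
            months_trying=int(self.months_trying[i]),
            diagnosed=bool(self.diagnosed[i]),
            uptake_decided=bool(self.uptake_decided[i]),
            uptake_accepted=bool(self.uptake_accepted[i]),
            track=TRACK_NAMES[self.track[i]],
            iui_cycles_used=int(self.iui_cycles_used[i]),
            ivf_cycles_used=int(self.ivf_cycles_used[i]),
        )


@dataclass
class Woman:
    """Readable snapshot of one woman's simulation state."""

    id: int
    education: str
    intended_family_size: int
    baseline_fecundability: float
    sterility_month: int
    uptake_probability: float
    parity: int = 0
    pregnant: bool = False
    gestation: int = 0
    months_trying: int = 0
    diagnosed: bool = False
    uptake_decided: bool = False
    uptake_accepted: bool = False
    track: str = "none"
    iui_cycles_used: int = 0
    ivf_cycles_used: int = 0
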