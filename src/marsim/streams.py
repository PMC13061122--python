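"""Counter-based random streams keyed by (seed, replicate, woman, month, channel).

Every stochastic decision in the simulator draws a uniform that is a pure
function of its key, never of how many draws happened before it.  This gives

* bitwise reproducibility for a given master seed,
* invariance to the order in which women are simulated and to cohort
  partitioning, and
* common random numbers across counterfactual scenario pairs: the draw that
  decides, say, a natural conception at month *m* for woman *w* is identical
  whether or not a policy lever changed her treatment history.

The hash is the splitmix64 finaliser, applied to successive xor-folds of the
key fields.  It is vectorised over women with numpy uint64 arithmetic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Channel", "CohortStreams", "WomanStream"]

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)
_M1 = _U64(0xBF58476D1CE4E5B9)
_M2 = _U64(0x94D049BB133111EB)
_WOMAN_SALT = _U64(0xD1342543DE82EF95)
_MONTH_SALT = _U64(0x2545F4914F6CDD1D)
_INV_2_53 = np.float64(2.0**-53)


class Channel:
    """Integer tags separating the independent decision streams."""

    ATTR_EDUCATION = 0
    ATTR_FAMILY_SIZE = 1
    ATTR_FECUNDABILITY = 2
    ATTR_STERILITY = 3
    ATTR_UPTAKE_INDEX = 4
    UNION = 5
    NATURAL_CONCEPTION = 6
    MAR_CYCLE = 7
    PREGNANCY_LOSS = 8
    PLURALITY = 9
    TWIN_TRIPLET = 10
    CONTRACEPTION = 11
    ABORTION = 12
    UPTAKE_DECISION = 13


def _mix(z):
    """splitmix64 finaliser (vectorised); wraps modulo 2**64."""
    z = np.asarray(z, dtype=_U64)  # 0-d arrays wrap silently, scalars warn
    with np.errstate(over="ignore"):
        z = z + _GOLDEN
        z = z ^ (z >> _U64(30))
        z = z * _M1
        z = z ^ (z >> _U64(27))
        z = z * _M2
        z = z ^ (z >> _U64(31))
    return z


class CohortStreams:
    """Keyed uniform draws for a cohort of women in one replicate."""

    def __init__(self, seed: int, replicate: int, woman_ids: np.ndarray):
        woman_ids = np.asarray(woman_ids, dtype=np.int64)
        if woman_ids.ndim != 1:
            raise ValueError("woman_ids must be one-dimensional")
        base = _mix(_U64(int(seed) & 0xFFFFFFFFFFFFFFFF))
        base = _mix(base ^ _U64(int(replicate)))
        self.seed = int(seed)
        self.replicate = int(replicate)
        self.woman_ids = woman_ids
        # per-woman 64-bit sub-keys
        self._wkey = _mix(base ^ (woman_ids.astype(_U64) * _WOMAN_SALT))

    def uniform(self, month: int, channel: int, index=None) -> np.ndarray:
        """Uniforms in [0, 1) for all women (or the subset ``index``)."""
        w = self._wkey if index is None else self._wkey[index]
        with np.errstate(over="ignore"):
            salted = _U64(int(month)) * _MONTH_SALT
        h = _mix(w ^ salted)
        h = _mix(h ^ _U64(int(channel)))
        return (h >> _U64(11)).astype(np.float64) * _INV_2_53

    def subset(self, index) -> "CohortStreams":
        """Streams restricted to a subset of women (keys unchanged)."""
        return CohortStreams(self.seed, self.replicate, self.woman_ids[index])


class WomanStream(CohortStreams):
    """Single-woman convenience wrapper returning python floats."""

    def __init__(self, seed: int, replicate: int, woman_id: int):
        super().__init__(seed, replicate, np.array([woman_id], dtype=np.int64))

    def draw(self, month: int, channel: int) -> float:
        return float(self.uniform(month, channel)[0])
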