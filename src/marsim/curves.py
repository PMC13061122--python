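"""Monthly age-indexed rate curves over the simulated reproductive span.

The simulation clock runs in months of age, from 15 years (month 180) to 55
years (month 660), with age measured at the start of the month.  An
:class:`AgeCurve` stores one probability-per-month value for each month of a
contiguous span.  Curves are built from sparse annual knots with a natural
cubic spline and clipped to [0, 1], mirroring how annual demographic and
clinical rate tables are turned into monthly schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

AGE_MIN_MONTHS = 180
AGE_MAX_MONTHS = 660
FULL_SPAN_MONTHS = AGE_MAX_MONTHS - AGE_MIN_MONTHS + 1

__all__ = [
    "AGE_MIN_MONTHS",
    "AGE_MAX_MONTHS",
    "AgeCurve",
    "interpolate_annual_to_monthly",
    "scale_treatment_curve",
]


@dataclass(frozen=True)
class AgeCurve:
    """Probability-per-month values on a contiguous grid of age months.

    Invariants (enforced at construction): the month index is contiguous and
    strictly increasing, lies within [180, 660], and every value is in [0, 1].
    """

    ages_months: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages_months, dtype=np.int64)
        vals = np.asarray(self.values, dtype=np.float64)
        if ages.ndim != 1 or vals.ndim != 1 or ages.size != vals.size:
            raise ValueError("ages_months and values must be 1-d and equal length")
        if ages.size == 0:
            raise ValueError("empty curve")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("month index must be contiguous and strictly increasing")
        if ages[0] < AGE_MIN_MONTHS or ages[-1] > AGE_MAX_MONTHS:
            raise ValueError(
                f"curve months [{ages[0]}, {ages[-1]}] outside simulated span "
                f"[{AGE_MIN_MONTHS}, {AGE_MAX_MONTHS}]"
            )
        if np.any(vals < 0.0) or np.any(vals > 1.0) or not np.all(np.isfinite(vals)):
            raise ValueError("curve values must be finite probabilities in [0, 1]")
        object.__setattr__(self, "ages_months", ages)
        object.__setattr__(self, "values", vals)

    # -- access ----------------------------------------------------------
    @property
    def start(self) -> int:
        return int(self.ages_months[0])

    @property
    def stop(self) -> int:
        return int(self.ages_months[-1])

    def covers_full_span(self) -> bool:
        return self.start == AGE_MIN_MONTHS and self.stop == AGE_MAX_MONTHS

    def at(self, month: int) -> float:
        """Value at one month of age (must lie inside the curve span)."""
        i = int(month) - self.start
        if i < 0 or i >= self.values.size:
            raise IndexError(f"month {month} outside curve span [{self.start}, {self.stop}]")
        return float(self.values[i])

    def lookup(self, months) -> np.ndarray:
        """Vectorised value lookup; months must lie inside the span."""
        idx = np.asarray(months, dtype=np.int64) - self.start
        if np.any(idx < 0) or np.any(idx >= self.values.size):
            raise IndexError("month outside curve span")
        return self.values[idx]

    def mean(self) -> float:
        return float(self.values.mean())

    # -- transforms ------------------------------------------------------
    def extended(self, start: int = AGE_MIN_MONTHS, stop: int = AGE_MAX_MONTHS) -> "AgeCurve":
        """Extend to [start, stop] holding the boundary values flat."""
        if start > self.start or stop < self.stop:
            raise ValueError("extended() only widens a curve")
        ages = np.arange(start, stop + 1)
        vals = np.empty(ages.size)
        vals[: self.start - start] = self.values[0]
        vals[self.start - start : self.stop - start + 1] = self.values
        vals[self.stop - start + 1 :] = self.values[-1]
        return AgeCurve(ages, vals)

    def scaled(self, factor: float) -> "AgeCurve":
        """Multiply every value by ``factor``, clipping to [0, 1]."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return AgeCurve(self.ages_months, np.clip(self.values * factor, 0.0, 1.0))

    # -- serialisation ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age_months": self.ages_months, "value": self.values})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AgeCurve":
        if "age_months" in frame.columns:
            return cls(frame["age_months"].to_numpy(), frame["value"].to_numpy())
        if "age_years" in frame.columns:  # annual table: spline it
            knots = dict(zip(frame["age_years"], frame["value"]))
            return interpolate_annual_to_monthly(knots)
        raise ValueError("curve table needs an 'age_months' or 'age_years' column")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AgeCurve)
            and np.array_equal(self.ages_months, other.ages_months)
            and np.array_equal(self.values, other.values)
        )


def interpolate_annual_to_monthly(annual_points: Mapping[float, float]) -> AgeCurve:
    """Spline sparse annual knots into a monthly curve.

    A natural cubic spline is fitted through the knots placed at
    ``year * 12`` months, evaluated at every month of the knot span, and
    clipped to [0, 1] to guard against overshoot at the edges.
    """
    if len(annual_points) < 3:
        raise ValueError("need at least 3 annual knots for cubic interpolation")
    years = np.array(sorted(annual_points), dtype=np.float64)
    vals = np.array([annual_points[y] for y in years], dtype=np.float64)
    if np.any(vals < 0.0) or np.any(vals > 1.0) or not np.all(np.isfinite(vals)):
        raise ValueError("annual knot values must be probabilities in [0, 1]")
    knot_months = years * 12.0
    if np.any(np.diff(knot_months) <= 0):
        raise ValueError("annual knot ages must be strictly increasing")
    spline = CubicSpline(knot_months, vals, bc_type="natural")
    months = np.arange(int(round(knot_months[0])), int(round(knot_months[-1])) + 1)
    out = np.clip(spline(months), 0.0, 1.0)
    return AgeCurve(months, out)


def scale_treatment_curve(
    reference: AgeCurve, target_mean: float, reference_mean: float
) -> AgeCurve:
    """Rescale a reference rate curve to a new mean level.

    Every point is multiplied by ``target_mean / reference_mean`` and clipped
    to [0, 1]; the age shape (ratios between any two ages) is preserved where
    no clipping occurs.
    """
    if reference_mean <= 0:
        raise ValueError("reference_mean must be positive")
    if target_mean < 0:
        raise ValueError("target_mean must be non-negative")
    return reference.scaled(target_mean / reference_mean)
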