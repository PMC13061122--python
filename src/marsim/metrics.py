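"""Cohort summary statistics: completed cohort fertility and MAR shares.

Completed cohort fertility (CCF) counts live-born *children* per woman (a
twin delivery contributes two), decomposed by maternal age group at
delivery.  MAR shares are the percentage of children conceived through each
treatment mode.  The net contribution of MAR is the CCF difference between a
run with treatment available and a paired run without it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .state import MAR_MODES, MODE_FET, MODE_IUI, MODE_IVF_ICSI, MODE_NAMES, MODE_NATURAL

# maternal age groups (label, first month inclusive, last month exclusive);
# the <20 group makes the decomposition exhaustive so groups sum to the total
AGE_GROUPS = (
    ("<20", 0, 240),
    ("20-24", 240, 300),
    ("25-29", 300, 360),
    ("30-34", 360, 420),
    ("35-39", 420, 480),
    ("40+", 480, 10**9),
)

UNDEFINED = float("nan")

__all__ = [
    "AGE_GROUPS",
    "CohortMetrics",
    "compute_metrics",
    "mar_share_of_ccf",
    "percent_reduction",
    "net_contribution",
]


@dataclass
class CohortMetrics:
    """All cohort summary statistics computed from the birth records."""

    cohort_size: int
    ccf: float
    ccf_by_age_group: dict
    children_by_mode: dict
    deliveries_by_mode: dict
    mar_children_per_woman: float
    mar_share_pct: float
    iui_share_pct: float
    art_share_pct: float
    mean_age_first_birth_years: float
    births_outside_union_pct: float
    multiple_birth_rate_by_mode: dict
    mar_use_by_education: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cohort_size": self.cohort_size,
            "ccf": self.ccf,
            "ccf_by_age_group": self.ccf_by_age_group,
            "children_by_mode": self.children_by_mode,
            "deliveries_by_mode": self.deliveries_by_mode,
            "mar_children_per_woman": self.mar_children_per_woman,
            "mar_share_pct": self.mar_share_pct,
            "iui_share_pct": self.iui_share_pct,
            "art_share_pct": self.art_share_pct,
            "mean_age_first_birth_years": self.mean_age_first_birth_years,
            "births_outside_union_pct": self.births_outside_union_pct,
            "multiple_birth_rate_by_mode": self.multiple_birth_rate_by_mode,
            "mar_use_by_education": self.mar_use_by_education,
        }


def compute_metrics(births: pd.DataFrame, cohort_size: int, women: Optional[pd.DataFrame] = None) -> CohortMetrics:
    """Summarise a cohort's birth records.

    ``births`` needs columns woman_id, age_months, plurality, mode, in_union;
    ``women`` (optional) adds education and treatment-use breakdowns.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    n_deliveries = len(births)
    plurality = births["plurality"].to_numpy() if n_deliveries else np.array([], dtype=int)
    mode = births["mode"].to_numpy() if n_deliveries else np.array([], dtype=int)
    age = births["age_months"].to_numpy() if n_deliveries else np.array([], dtype=int)
    children = int(plurality.sum())
    ccf = children / cohort_size

    by_group = {}
    for label, lo, hi in AGE_GROUPS:
        sel = (age >= lo) & (age < hi)
        by_group[label] = float(plurality[sel].sum() / cohort_size)
    # exhaustive, disjoint age groups: conservation must hold exactly
    assert abs(sum(by_group.values()) - ccf) < 1e-9, "age-group CCFs do not sum to total"

    children_by_mode = {}
    deliveries_by_mode = {}
    multiple_by_mode = {}
    for code, name in MODE_NAMES.items():
        sel = mode == code
        children_by_mode[name] = int(plurality[sel].sum())
        deliveries_by_mode[name] = int(sel.sum())
        multiple_by_mode[name] = float((plurality[sel] >= 2).mean()) if sel.any() else UNDEFINED

    mar_children = sum(children_by_mode[MODE_NAMES[m]] for m in MAR_MODES)
    art_children = children_by_mode[MODE_NAMES[MODE_IVF_ICSI]] + children_by_mode[MODE_NAMES[MODE_FET]]
    iui_children = children_by_mode[MODE_NAMES[MODE_IUI]]

    if n_deliveries:
        first = births.groupby("woman_id")["age_months"].min()
        mean_age_first = float(first.mean() / 12.0)
        outside_pct = float(100.0 * (~births["in_union"]).mean())
    else:
        mean_age_first = UNDEFINED
        outside_pct = 0.0

    mar_use_by_education = {}
    if women is not None and "education" in women.columns and len(women):
        for edu, grp in women.groupby("education", observed=True):
            mar_use_by_education[edu] = float(grp["ever_treated"].mean())

    return CohortMetrics(
        cohort_size=cohort_size,
        ccf=ccf,
        ccf_by_age_group=by_group,
        children_by_mode=children_by_mode,
        deliveries_by_mode=deliveries_by_mode,
        mar_children_per_woman=mar_children / cohort_size,
        mar_share_pct=100.0 * mar_children / children if children else 0.0,
        iui_share_pct=100.0 * iui_children / children if children else 0.0,
        art_share_pct=100.0 * art_children / children if children else 0.0,
        mean_age_first_birth_years=mean_age_first,
        births_outside_union_pct=outside_pct,
        multiple_birth_rate_by_mode=multiple_by_mode,
        mar_use_by_education=mar_use_by_education,
    )


def mar_share_of_ccf(metrics_or_mar_per_woman, ccf: Optional[float] = None) -> float:
    """MAR-conceived children as a percentage of CCF.

    Accepts either a :class:`CohortMetrics` or the pair
    ``(mar_children_per_woman, ccf)``.  Undefined (NaN) when CCF is zero.
    """
    if isinstance(metrics_or_mar_per_woman, CohortMetrics):
        mar = metrics_or_mar_per_woman.mar_children_per_woman
        ccf = metrics_or_mar_per_woman.ccf
    else:
        mar = float(metrics_or_mar_per_woman)
        if ccf is None:
            raise ValueError("ccf required when passing a per-woman value")
    if ccf == 0:
        return UNDEFINED
    return 100.0 * mar / ccf


def percent_reduction(observed_share_per_woman: float, net_contribution_per_woman: float) -> float:
    """How much smaller the net contribution is than the observed share (%).

    Undefined (NaN) when the observed share is zero.
    """
    if observed_share_per_woman == 0:
        return UNDEFINED
    return 100.0 * (observed_share_per_woman - net_contribution_per_woman) / observed_share_per_woman


def net_contribution(metrics_with: CohortMetrics, metrics_without: CohortMetrics) -> pd.DataFrame:
    """Net contribution of MAR: paired with-vs-without CCF differences.

    One row for the total and one per maternal age group, with absolute
    (CCF_with - CCF_without) and relative (100 x absolute / CCF_without)
    contributions.  A relative contribution with a zero denominator and a
    nonzero numerator is reported as NaN, not infinity.
    """
    if metrics_with.cohort_size != metrics_without.cohort_size:
        raise ValueError("paired runs must share the cohort size")
    rows = []

    def row(label, w, wo):
        absolute = w - wo
        if wo == 0:
            relative = 0.0 if absolute == 0 else UNDEFINED
        else:
            relative = 100.0 * absolute / wo
        rows.append({"group": label, "ccf_without": wo, "ccf_with": w, "absolute": absolute, "relative_pct": relative})

    row("total", metrics_with.ccf, metrics_without.ccf)
    for label, _, _ in AGE_GROUPS:
        row(label, metrics_with.ccf_by_age_group[label], metrics_without.ccf_by_age_group[label])
    return pd.DataFrame(rows)
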