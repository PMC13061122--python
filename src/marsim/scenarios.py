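"""Counterfactual scenario levers and sweep experiments.

A :class:`ScenarioConfig` holds overrides applied on top of a baseline
parameter set: the uptake share, the reimbursement age window, waiting
times, cycle limits, the time to infertility diagnosis, the IUI rate level,
and the cohabitation-postponement shift.  Sweeps run one paired cohort per
grid point with common random numbers against the baseline, so lever effects
are resolved at desk-scale cohort sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import pandas as pd

from .metrics import compute_metrics, mar_share_of_ccf, net_contribution
from .parameters import ParameterSet

__all__ = [
    "UNSET",
    "ScenarioConfig",
    "apply_scenario",
    "sweep",
    "net_contribution_runs",
    "ideal_mar_experiment",
]


class _Unset:
    """Sentinel: lever not overridden (distinct from None = 'no limit')."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "UNSET"

    def __bool__(self):
        return False


UNSET = _Unset()

# documented lever ranges (inclusive); None means the value may also be None
_LEVER_RANGES = {
    "uptake_share": (0.0, 1.0),
    "max_age_at_mar_years": (15, 60),
    "min_age_at_mar_years": (15, 55),
    "added_months_to_diagnosis": (0, 24),
    "wait_first_iui_months": (1, 12),
    "wait_between_iui_months": (1, 12),
    "wait_first_ivf_months": (1, 12),
    "wait_between_ivf_months": (1, 12),
    "max_iui_cycles": (0, 6),
    "max_ivf_icsi_cycles": (0, 6),
    "iui_rate_scale": (0.0, 5.0),
    "cohabitation_shift_months": (0, 240),
}


@dataclass
class ScenarioConfig:
    """Lever overrides on top of a baseline parameter set."""

    uptake_share: object = UNSET  # float in [0, 1]
    max_age_at_mar_years: object = UNSET  # int, or None for no upper limit
    min_age_at_mar_years: object = UNSET  # int, or None for no lower limit
    added_months_to_diagnosis: object = UNSET  # int, added to the baseline 12
    wait_first_iui_months: object = UNSET
    wait_between_iui_months: object = UNSET
    wait_first_ivf_months: object = UNSET
    wait_between_ivf_months: object = UNSET
    max_iui_cycles: object = UNSET
    max_ivf_icsi_cycles: object = UNSET
    iui_rate_scale: object = UNSET  # multiplies the IUI per-cycle rate curve
    cohabitation_shift_months: object = UNSET
    mar_enabled: object = UNSET  # bool

    def overrides(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self) if getattr(self, f.name) is not UNSET}

    def validate(self) -> None:
        for name, value in self.overrides().items():
            if name == "mar_enabled":
                if not isinstance(value, (bool,)):
                    raise ValueError("lever 'mar_enabled' must be a bool")
                continue
            if value is None:
                if name in ("max_age_at_mar_years", "min_age_at_mar_years"):
                    continue
                raise ValueError(f"lever '{name}' cannot be None")
            lo, hi = _LEVER_RANGES[name]
            if not (lo <= value <= hi):
                raise ValueError(f"lever '{name}'={value} outside documented range [{lo}, {hi}]")


def apply_scenario(params: ParameterSet, scenario: ScenarioConfig) -> ParameterSet:
    """Return a modified copy of the parameter set; the baseline is untouched."""
    scenario.validate()
    out = params.copy()
    ov = scenario.overrides()
    th = out.thresholds
    if "uptake_share" in ov:
        out.uptake_share = float(ov["uptake_share"])
    if "max_age_at_mar_years" in ov:
        th.max_age_at_mar_years = ov["max_age_at_mar_years"]
    if "min_age_at_mar_years" in ov:
        th.min_age_at_mar_years = ov["min_age_at_mar_years"]
    if "added_months_to_diagnosis" in ov:
        th.diagnosis_min_months_trying = params.thresholds.diagnosis_min_months_trying + int(
            ov["added_months_to_diagnosis"]
        )
    for key in (
        "wait_first_iui_months",
        "wait_between_iui_months",
        "wait_first_ivf_months",
        "wait_between_ivf_months",
        "max_iui_cycles",
        "max_ivf_icsi_cycles",
    ):
        if key in ov:
            setattr(th, key, int(ov[key]))
    if "iui_rate_scale" in ov:
        out.treatment.iui = out.treatment.iui.scaled(float(ov["iui_rate_scale"]))
    if "cohabitation_shift_months" in ov:
        out.cohabitation_shift_months = int(ov["cohabitation_shift_months"])
    if "mar_enabled" in ov:
        out.mar_enabled = bool(ov["mar_enabled"])
    return out


def _run_point(base_config, scenario: ScenarioConfig):
    from .engine import RunConfig, run_cohort

    config = RunConfig(
        cohort_size=base_config.cohort_size,
        seed=base_config.seed,
        params=base_config.params,
        scenario=scenario,
        log_events=False,
    )
    return run_cohort(config).metrics()


def sweep(lever_grid: dict, run_config) -> pd.DataFrame:
    """Run one paired cohort per grid point (cartesian product of levers).

    All points share the master seed, so differences between rows are driven
    by the levers under common random numbers, not by Monte Carlo noise.
    Returns a tidy table: one row per grid point with the lever values and
    the headline metrics.
    """
    if not lever_grid:
        raise ValueError("lever grid must not be empty")
    names = list(lever_grid)
    rows = []
    for combo in itertools.product(*(lever_grid[k] for k in names)):
        scenario = ScenarioConfig(**dict(zip(names, combo)))
        m = _run_point(run_config, scenario)
        row = dict(zip(names, combo))
        row.update(
            ccf=m.ccf,
            mar_children_per_woman=m.mar_children_per_woman,
            mar_share_pct=m.mar_share_pct,
            iui_share_pct=m.iui_share_pct,
            art_share_pct=m.art_share_pct,
            mean_age_first_birth_years=m.mean_age_first_birth_years,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def net_contribution_runs(run_config):
    """Baseline vs MAR-unavailable paired runs (common random numbers).

    Returns ``(metrics_with, metrics_without, contribution_table)``.
    """
    metrics_with = _run_point(run_config, ScenarioConfig())
    metrics_without = _run_point(run_config, ScenarioConfig(mar_enabled=False))
    return metrics_with, metrics_without, net_contribution(metrics_with, metrics_without)


def ideal_mar_experiment(shifts: Sequence[int], run_config) -> pd.DataFrame:
    """Cohabitation postponement under an 'ideal' treatment regime.

    For each shift (months added to the age at first cohabitation) the
    cohort is run with 100% uptake among the eligible and no upper age limit
    on treatment.  Reports CCF, mean age at first birth, and the MAR share
    of CCF per shift.
    """
    rows = []
    for shift in shifts:
        scenario = ScenarioConfig(
            uptake_share=1.0, max_age_at_mar_years=None, cohabitation_shift_months=int(shift)
        )
        m = _run_point(run_config, scenario)
        rows.append(
            {
                "shift_months": int(shift),
                "ccf": m.ccf,
                "mean_age_first_birth_years": m.mean_age_first_birth_years,
                "mar_share_of_ccf_pct": mar_share_of_ccf(m),
            }
        )
    return pd.DataFrame(rows)
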