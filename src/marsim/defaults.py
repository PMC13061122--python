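"""Packaged synthetic default parameter set and small test fixtures.

The defaults are smooth parametric stand-ins with the documented structure
of the Dutch 1974-1984 cohort inputs: fecundability peaks in the twenties
and declines steeply after 35; per-cycle treatment success declines with
age; intrauterine mortality and the multiple-birth probability rise with
age; union formation peaks in the mid-twenties, later for tertiary-educated
women; treatment uptake is bootstrapped around 73% (n = 825).  Every default
number lives in the annual knot tables below (also shipped as CSV/YAML under
``data/``), never hard-coded in simulation logic.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .curves import AgeCurve, interpolate_annual_to_monthly, scale_treatment_curve
from .metrics import CohortMetrics
from .parameters import (
    Contraception,
    FecundabilityModel,
    MultipleBirthModel,
    ParameterSet,
    SterilityModel,
    Thresholds,
    TreatmentRates,
    UnionHazards,
    bootstrap_uptake,
    build_multiple_birth_model,
)
from .state import MODE_FET, MODE_IUI, MODE_IVF_ICSI, MODE_NATURAL

__all__ = ["default_parameter_set", "write_default_tables", "toy_cohort_fixture"]

# ---------------------------------------------------------------------------
# annual knot tables (age in years -> value); splined to monthly curves
# ---------------------------------------------------------------------------

FECUNDABILITY_DECLINE_KNOTS = {
    15: 0.55, 18: 0.90, 21: 1.00, 25: 1.00, 28: 1.00, 30: 0.96, 33: 0.86,
    35: 0.75, 37: 0.63, 40: 0.40, 42: 0.26, 44: 0.14, 46: 0.07, 48: 0.03,
    50: 0.01, 52: 0.0, 55: 0.0,
}
# population heterogeneity of baseline fecundability: scale * Beta(a, b);
# the heavy low tail (a < 1) carries the subfertile couples who reach ART
FECUNDABILITY_BETA = {"beta_a": 0.9, "beta_b": 3.6, "scale": 1.0}  # mean 0.20

INTRAUTERINE_MORTALITY_KNOTS = {
    15: 0.18, 20: 0.13, 25: 0.11, 30: 0.12, 33: 0.14, 35: 0.17, 38: 0.23,
    40: 0.30, 42: 0.38, 44: 0.47, 46: 0.55, 50: 0.70, 55: 0.85,
}

STERILITY_CDF_KNOTS = {
    15: 0.008, 20: 0.012, 25: 0.02, 30: 0.04, 34: 0.07, 37: 0.11, 39: 0.16,
    41: 0.24, 43: 0.36, 45: 0.52, 47: 0.70, 49: 0.86, 51: 0.96, 53: 0.995, 55: 1.0,
}

# "union" formation marks the start of joint conception attempts, so the
# schedules sit close to observed first-birth timing minus one waiting year
UNION_FORMATION_KNOTS = {
    "primary": {
        15: 0.0, 19: 0.002, 21: 0.005, 24: 0.013, 27: 0.019, 30: 0.016, 33: 0.011,
        37: 0.006, 41: 0.0035, 45: 0.002, 49: 0.0012, 55: 0.0008,
    },
    "secondary": {
        15: 0.0, 20: 0.002, 22: 0.004, 25: 0.011, 28: 0.019, 31: 0.016, 34: 0.011,
        37: 0.006, 41: 0.0035, 45: 0.002, 49: 0.0012, 55: 0.0008,
    },
    "tertiary": {
        15: 0.0, 21: 0.001, 23: 0.003, 26: 0.009, 29: 0.018, 32: 0.017, 35: 0.011,
        38: 0.006, 42: 0.0035, 46: 0.002, 50: 0.0012, 55: 0.0008,
    },
}
UNION_DISSOLUTION_KNOTS = {
    "primary": {15: 0.006, 20: 0.0054, 25: 0.0048, 30: 0.0038, 35: 0.0031, 40: 0.0024, 45: 0.0018, 50: 0.0014, 55: 0.0012},
    "secondary": {15: 0.005, 20: 0.0045, 25: 0.004, 30: 0.0032, 35: 0.0026, 40: 0.002, 45: 0.0015, 50: 0.0012, 55: 0.001},
    "tertiary": {15: 0.0042, 20: 0.0038, 25: 0.0034, 30: 0.0027, 35: 0.0022, 40: 0.0017, 45: 0.0013, 50: 0.001, 55: 0.0009},
}

# per-cycle pregnancy rates: IVF is the reference curve, others ratio-scaled
IVF_RATE_KNOTS = {
    15: 0.26, 20: 0.28, 25: 0.29, 28: 0.285, 30: 0.27, 32: 0.25, 34: 0.23,
    36: 0.20, 38: 0.16, 40: 0.11, 42: 0.06, 44: 0.025, 46: 0.012, 50: 0.004, 55: 0.001,
}
TREATMENT_MEAN_RATES = {"IUI": 0.015, "IVF": 0.24, "ICSI": 0.24, "FET": 0.17}

# multiple births: register-style all-births curve, treated fraction, means
ALL_BIRTHS_MULTIPLE_KNOTS = {
    15: 0.010, 20: 0.011, 25: 0.013, 30: 0.016, 33: 0.019, 36: 0.023, 38: 0.025,
    40: 0.024, 43: 0.020, 46: 0.017, 50: 0.015, 55: 0.014,
}
MAR_BIRTH_FRACTION_KNOTS = {
    15: 0.0, 20: 0.002, 25: 0.01, 30: 0.03, 33: 0.055, 35: 0.075, 37: 0.095,
    39: 0.11, 41: 0.12, 43: 0.12, 45: 0.06, 47: 0.02, 50: 0.0, 55: 0.0,
}
TREATMENT_MULTIPLE_MEANS = {"IUI": 0.08, "IVF": 0.15, "ICSI": 0.15, "FET": 0.07}
NATURAL_MULTIPLE_MEAN = 0.015
TWIN_TRIPLET_COUNTS = (9700, 300)

EDUCATION_DISTRIBUTION = {"primary": 0.25, "secondary": 0.40, "tertiary": 0.35}
INTENDED_FAMILY_SIZE_DISTRIBUTION = {0: 0.10, 1: 0.15, 2: 0.50, 3: 0.19, 4: 0.06}
CONTRACEPTION = {"monthly_failure": 0.004, "abortion_probability": 0.5}

UPTAKE_MEAN = 0.73
UPTAKE_N = 825
UPTAKE_DRAWS = 10_000


def _monotone(curve: AgeCurve) -> AgeCurve:
    """Force a CDF-like curve non-decreasing (spline wiggle guard)."""
    return AgeCurve(curve.ages_months, np.minimum(np.maximum.accumulate(curve.values), 1.0))


def default_parameter_set(seed: int = 0, uptake_draws: int = UPTAKE_DRAWS) -> ParameterSet:
    """Deterministic construction of the packaged synthetic defaults.

    ``seed`` drives only the uptake bootstrap; the curves themselves are a
    deterministic function of the knot tables.  Thresholds carry the
    documented clinical values (ART gate 0.0077, 58% twelve-month prognosis
    threshold below age 38, diagnosis after 12 months trying, treatment up
    to age 43, six IUI and three IVF/ICSI cycles).
    """
    ivf = interpolate_annual_to_monthly(IVF_RATE_KNOTS)
    ref_mean = TREATMENT_MEAN_RATES["IVF"]
    treatment = TreatmentRates(
        iui=scale_treatment_curve(ivf, TREATMENT_MEAN_RATES["IUI"], ref_mean),
        ivf=ivf,
        icsi=scale_treatment_curve(ivf, TREATMENT_MEAN_RATES["ICSI"], ref_mean),
        fet=scale_treatment_curve(ivf, TREATMENT_MEAN_RATES["FET"], ref_mean),
    )
    multiple_birth = build_multiple_birth_model(
        all_births_curve=interpolate_annual_to_monthly(ALL_BIRTHS_MULTIPLE_KNOTS),
        mar_birth_fraction_by_age=interpolate_annual_to_monthly(MAR_BIRTH_FRACTION_KNOTS),
        treatment_means=TREATMENT_MULTIPLE_MEANS,
        natural_mean=NATURAL_MULTIPLE_MEAN,
        twin_triplet_counts=TWIN_TRIPLET_COUNTS,
    )
    params = ParameterSet(
        fecundability=FecundabilityModel(
            decline=interpolate_annual_to_monthly(FECUNDABILITY_DECLINE_KNOTS), **FECUNDABILITY_BETA
        ),
        intrauterine_mortality=interpolate_annual_to_monthly(INTRAUTERINE_MORTALITY_KNOTS),
        sterility=SterilityModel(cdf=_monotone(interpolate_annual_to_monthly(STERILITY_CDF_KNOTS))),
        unions=UnionHazards(
            formation={e: interpolate_annual_to_monthly(k) for e, k in UNION_FORMATION_KNOTS.items()},
            dissolution={e: interpolate_annual_to_monthly(k) for e, k in UNION_DISSOLUTION_KNOTS.items()},
        ),
        education_distribution=dict(EDUCATION_DISTRIBUTION),
        intended_family_size_distribution=dict(INTENDED_FAMILY_SIZE_DISTRIBUTION),
        contraception=Contraception(**CONTRACEPTION),
        treatment=treatment,
        multiple_birth=multiple_birth,
        uptake=bootstrap_uptake(UPTAKE_MEAN, UPTAKE_N, draws=uptake_draws, seed=seed),
        thresholds=Thresholds(),
    )
    params.validate()
    return params


# ---------------------------------------------------------------------------
# packaged knot tables (data/): regenerated by `marsim fixtures`
# ---------------------------------------------------------------------------

_KNOT_FILES = {
    "fecundability_decline": lambda: FECUNDABILITY_DECLINE_KNOTS,
    "intrauterine_mortality": lambda: INTRAUTERINE_MORTALITY_KNOTS,
    "sterility_cdf": lambda: STERILITY_CDF_KNOTS,
    "ivf_rate": lambda: IVF_RATE_KNOTS,
    "all_births_multiple": lambda: ALL_BIRTHS_MULTIPLE_KNOTS,
    "mar_birth_fraction": lambda: MAR_BIRTH_FRACTION_KNOTS,
    **{
        f"union_formation_{edu}": (lambda e=edu: UNION_FORMATION_KNOTS[e])
        for edu in UNION_FORMATION_KNOTS
    },
    **{
        f"union_dissolution_{edu}": (lambda e=edu: UNION_DISSOLUTION_KNOTS[e])
        for edu in UNION_DISSOLUTION_KNOTS
    },
}


def write_default_tables(directory) -> None:
    """Write the default knot tables and scalar config as CSV/YAML."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    for name, getter in _KNOT_FILES.items():
        knots = getter()
        pd.DataFrame({"age_years": list(knots), "value": list(knots.values())}).to_csv(
            root / f"{name}.csv", index=False
        )
    scalars = {
        "fecundability_beta": FECUNDABILITY_BETA,
        "treatment_mean_rates": TREATMENT_MEAN_RATES,
        "treatment_multiple_means": TREATMENT_MULTIPLE_MEANS,
        "natural_multiple_mean": NATURAL_MULTIPLE_MEAN,
        "twin_triplet_counts": list(TWIN_TRIPLET_COUNTS),
        "education_distribution": EDUCATION_DISTRIBUTION,
        "intended_family_size_distribution": INTENDED_FAMILY_SIZE_DISTRIBUTION,
        "contraception": CONTRACEPTION,
        "uptake": {"mean": UPTAKE_MEAN, "n": UPTAKE_N, "draws": UPTAKE_DRAWS},
        "thresholds": {
            "art_fecundability_gate": 0.0077,
            "entry_cum12_threshold": 0.58,
            "entry_check_max_age_years": 38,
            "diagnosis_min_months_trying": 12,
            "max_age_at_mar_years": 43,
            "max_iui_cycles": 6,
            "max_ivf_icsi_cycles": 3,
        },
    }
    with open(root / "defaults.yaml", "w") as fh:
        yaml.safe_dump(scalars, fh, sort_keys=False)


def packaged_data_dir() -> Path:
    return Path(importlib.resources.files("marsim") / "data")


# ---------------------------------------------------------------------------
# hand-built 20-woman fixture with every event type represented
# ---------------------------------------------------------------------------


def toy_cohort_fixture():
    """A 20-woman cohort with hand-computed expected metrics.

    Contains a twin treatment birth, a treatment pregnancy lost to
    intrauterine mortality with a reimbursement reset, and a union
    dissolution during pregnancy (a birth outside a union).  Returns
    ``(births, women, events, expected)`` where ``expected`` is the
    hand-computed :class:`~marsim.metrics.CohortMetrics`.
    """
    births = pd.DataFrame(
        [
            # woman_id, age_months, plurality, mode, in_union
            (0, 300, 1, MODE_NATURAL, True),
            (0, 340, 1, MODE_NATURAL, True),
            (1, 310, 2, MODE_IVF_ICSI, True),  # twin treatment birth
            (2, 250, 1, MODE_NATURAL, True),
            (3, 420, 1, MODE_IUI, True),
            (4, 455, 1, MODE_FET, True),
            (5, 380, 1, MODE_NATURAL, False),  # union dissolved during pregnancy
            (6, 290, 3, MODE_NATURAL, True),
            (7, 360, 1, MODE_NATURAL, True),
            (8, 230, 1, MODE_NATURAL, True),
            (9, 490, 1, MODE_IVF_ICSI, True),
        ],
        columns=["woman_id", "age_months", "plurality", "mode", "in_union"],
    )
    education = {
        **{w: "tertiary" for w in (0, 1, 3, 4, 9, 10)},
        **{w: "primary" for w in (2, 5, 11, 12)},
    }
    treated = {1, 3, 4, 9, 10}
    women = pd.DataFrame(
        {
            "woman_id": range(20),
            "education": [education.get(w, "secondary") for w in range(20)],
            "ever_treated": [w in treated for w in range(20)],
        }
    )
    events = pd.DataFrame(
        [
            (398, 3, "conception", float(MODE_IUI)),
            (400, 3, "intrauterine_mortality", float(MODE_IUI)),
            (400, 3, "reimbursement_reset", 0.0),
            (371, 5, "union_dissolution", 0.0),
            (380, 5, "birth", 1.0),
        ],
        columns=["month", "woman_id", "event", "value"],
    )
    expected = CohortMetrics(
        cohort_size=20,
        ccf=0.70,
        ccf_by_age_group={"<20": 0.05, "20-24": 0.20, "25-29": 0.20, "30-34": 0.10, "35-39": 0.10, "40+": 0.05},
        children_by_mode={"natural": 9, "IUI": 1, "IVF-ICSI": 3, "FET": 1},
        deliveries_by_mode={"natural": 7, "IUI": 1, "IVF-ICSI": 2, "FET": 1},
        mar_children_per_woman=0.25,
        mar_share_pct=100.0 * 5 / 14,
        iui_share_pct=100.0 * 1 / 14,
        art_share_pct=100.0 * 4 / 14,
        mean_age_first_birth_years=3485 / 10 / 12.0,
        births_outside_union_pct=100.0 * 1 / 11,
        multiple_birth_rate_by_mode={"natural": 1 / 7, "IUI": 0.0, "IVF-ICSI": 0.5, "FET": 0.0},
        mar_use_by_education={"primary": 0.0, "secondary": 0.0, "tertiary": 5 / 6},
    )
    return births, women, events, expected
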