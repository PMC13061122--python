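"""Shared fixtures: synthetic default parameters and controllable toy parameter sets."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from marsim.curves import AGE_MAX_MONTHS, AGE_MIN_MONTHS, AgeCurve
from marsim.defaults import default_parameter_set
from marsim.parameters import (
    Contraception,
    FecundabilityModel,
    MultipleBirthModel,
    ParameterSet,
    SterilityModel,
    Thresholds,
    TreatmentRates,
    UnionHazards,
    UptakeDistribution,
)


def constant_curve(value: float) -> AgeCurve:
    months = np.arange(AGE_MIN_MONTHS, AGE_MAX_MONTHS + 1)
    return AgeCurve(months, np.full(months.size, float(value)))


def pulse_curve(month: int, value: float = 1.0, elsewhere: float = 0.0) -> AgeCurve:
    months = np.arange(AGE_MIN_MONTHS, AGE_MAX_MONTHS + 1)
    vals = np.full(months.size, float(elsewhere))
    vals[month - AGE_MIN_MONTHS] = value
    return AgeCurve(months, vals)


def make_params(
    fecundability: float = 0.2,
    decline: AgeCurve | None = None,
    mortality: float = 0.0,
    formation: AgeCurve | None = None,
    dissolution: AgeCurve | None = None,
    iui_rate: float = 0.0,
    ivf_rate: float = 0.0,
    fet_rate: float = 0.0,
    multiple_p: float = 0.0,
    twin_triplet_ratio: float = 10.0,
    intended_family_size: dict | None = None,
    contraception_failure: float = 0.0,
    abortion_probability: float = 0.0,
    uptake_probability: float = 1.0,
    mar_enabled: bool = True,
    **threshold_overrides,
) -> ParameterSet:
    """A fully valid parameter set with flat, exactly controllable curves.

    Baseline fecundability is (numerically) a point mass at ``fecundability``
    via an extremely concentrated Beta distribution.
    """
    formation = formation if formation is not None else constant_curve(0.02)
    dissolution = dissolution if dissolution is not None else constant_curve(0.0)
    conc = 2e6
    params = ParameterSet(
        fecundability=FecundabilityModel(
            beta_a=conc * max(fecundability, 1e-9),
            beta_b=conc * max(1.0 - fecundability, 1e-9),
            scale=1.0,
            decline=decline if decline is not None else constant_curve(1.0),
        ),
        intrauterine_mortality=constant_curve(mortality),
        sterility=SterilityModel(cdf=constant_curve(0.0)),
        unions=UnionHazards(
            formation={e: formation for e in ("primary", "secondary", "tertiary")},
            dissolution={e: dissolution for e in ("primary", "secondary", "tertiary")},
        ),
        education_distribution={"primary": 0.3, "secondary": 0.4, "tertiary": 0.3},
        intended_family_size_distribution=intended_family_size or {2: 1.0},
        contraception=Contraception(
            monthly_failure=contraception_failure, abortion_probability=abortion_probability
        ),
        treatment=TreatmentRates(
            iui=constant_curve(iui_rate),
            ivf=constant_curve(ivf_rate),
            icsi=constant_curve(ivf_rate),
            fet=constant_curve(fet_rate),
        ),
        multiple_birth=MultipleBirthModel(
            natural=constant_curve(multiple_p),
            ratios={"IUI": 1.0, "IVF": 1.0, "ICSI": 1.0, "FET": 1.0},
            twin_triplet_ratio=twin_triplet_ratio,
        ),
        uptake=UptakeDistribution(
            draws=np.array([uptake_probability]), source_mean=uptake_probability, source_n=2
        ),
        thresholds=replace(Thresholds(), **threshold_overrides),
        mar_enabled=mar_enabled,
    )
    params.validate()
    return params


@pytest.fixture(scope="session")
def default_params():
    return default_parameter_set()
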