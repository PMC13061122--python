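"""Parameter set for one simulation run: rate curves, distributions, thresholds.

A :class:`ParameterSet` bundles everything one cohort run consumes: the
fecundability model (population heterogeneity plus age decline), intrauterine
mortality, sterility onset, union formation/dissolution hazards by education,
intended-family-size and education distributions, contraception behaviour,
per-cycle treatment success curves for the four MAR treatment types, the
multiple-birth model, the bootstrapped uptake distribution, and the clinical
thresholds and cycle limits of the treatment pathway.

Serialisation is a directory: a ``parameters.yaml`` master config plus one
plain CSV per curve, so every number a run uses is inspectable and swappable.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .curves import (
    AGE_MAX_MONTHS,
    AGE_MIN_MONTHS,
    AgeCurve,
    interpolate_annual_to_monthly,
    scale_treatment_curve,
)

log = logging.getLogger(__name__)

EDUCATION_LEVELS = ("primary", "secondary", "tertiary")
TREATMENT_TYPES = ("IUI", "IVF", "ICSI", "FET")
NEVER = 10**6  # sterility-onset sentinel: beyond the simulated span

__all__ = [
    "EDUCATION_LEVELS",
    "TREATMENT_TYPES",
    "ParameterValidationError",
    "FecundabilityModel",
    "SterilityModel",
    "UnionHazards",
    "TreatmentRates",
    "MultipleBirthModel",
    "UptakeDistribution",
    "Thresholds",
    "Contraception",
    "ParameterSet",
    "bootstrap_uptake",
    "build_multiple_birth_model",
    "cumulative_conception_probability",
    "load_parameters",
    "save_parameters",
]


class ParameterValidationError(ValueError):
    """A parameter table or config failed schema validation."""


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping or mapping[key] is None:
        raise ParameterValidationError(f"missing required field '{key}' in {context}")
    return mapping[key]


# ---------------------------------------------------------------------------
# component models
# ---------------------------------------------------------------------------


@dataclass
class FecundabilityModel:
    """Population heterogeneity in baseline fecundability plus age decline.

    Baseline fecundability (the monthly conception probability at peak age,
    without contraception) is ``scale * Beta(beta_a, beta_b)`` across women;
    the ``decline`` curve is a dimensionless multiplier by age (1 at peak).
    """

    beta_a: float
    beta_b: float
    scale: float
    decline: AgeCurve

    def sample_baseline(self, u: np.ndarray) -> np.ndarray:
        """Inverse-CDF draw of baseline fecundability from uniforms."""
        return self.scale * stats.beta.ppf(u, self.beta_a, self.beta_b)

    def mean_baseline(self) -> float:
        return self.scale * self.beta_a / (self.beta_a + self.beta_b)


@dataclass
class SterilityModel:
    """Age at onset of permanent sterility, as a CDF over age months."""

    cdf: AgeCurve  # non-decreasing; P(onset <= age)

    def sample_onset(self, u: np.ndarray) -> np.ndarray:
        """Month of sterility onset per woman (NEVER if beyond the span)."""
        idx = np.searchsorted(self.cdf.values, u, side="left")
        onset = np.where(
            idx >= self.cdf.values.size, NEVER, self.cdf.ages_months[np.minimum(idx, self.cdf.values.size - 1)]
        )
        return onset.astype(np.int64)


@dataclass
class UnionHazards:
    """Monthly union formation and dissolution hazards by education."""

    formation: dict
    dissolution: dict


@dataclass
class TreatmentRates:
    """Per-cycle pregnancy-rate curve for each MAR treatment type.

    The IVF curve is the reference; the other types are ratio-scaled copies
    of it (same age shape, different mean level).
    """

    iui: AgeCurve
    ivf: AgeCurve
    icsi: AgeCurve
    fet: AgeCurve

    def curve(self, name: str) -> AgeCurve:
        return {"IUI": self.iui, "IVF": self.ivf, "ICSI": self.icsi, "FET": self.fet}[name]


@dataclass
class MultipleBirthModel:
    """Probability of a multiple delivery, by age and conception mode."""

    natural: AgeCurve
    ratios: dict  # treatment type -> dimensionless ratio vs natural
    twin_triplet_ratio: float  # twins per triplet among multiple deliveries

    def curve(self, mode: str) -> AgeCurve:
        """Multiple-birth curve for a conception mode (natural or a type)."""
        if mode in ("natural", "NATURAL"):
            return self.natural
        return self.natural.scaled(self.ratios[mode])

    def twin_probability(self) -> float:
        """P(twins | multiple delivery) = k / (k + 1)."""
        k = self.twin_triplet_ratio
        return k / (k + 1.0)


@dataclass
class UptakeDistribution:
    """Bootstrapped distribution of the MAR uptake probability."""

    draws: np.ndarray
    source_mean: float
    source_n: int

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=np.float64)
        if self.draws.ndim != 1 or self.draws.size < 1:
            raise ParameterValidationError("uptake draws must be a non-empty vector")
        if np.any(self.draws < 0) or np.any(self.draws > 1):
            raise ParameterValidationError("uptake draws must lie in [0, 1]")

    def mean(self) -> float:
        return float(self.draws.mean())

    def assign(self, u: np.ndarray) -> np.ndarray:
        """Pick one draw per woman from a uniform."""
        idx = np.minimum((u * self.draws.size).astype(np.int64), self.draws.size - 1)
        return self.draws[idx]


# thresholds required to be present in any config file
_REQUIRED_THRESHOLDS = (
    "art_fecundability_gate",
    "entry_cum12_threshold",
    "entry_check_max_age_years",
    "diagnosis_min_months_trying",
    "max_age_at_mar_years",
    "max_iui_cycles",
    "max_ivf_icsi_cycles",
)


@dataclass
class Thresholds:
    """Clinical thresholds, cycle limits, and waiting times of the pathway."""

    art_fecundability_gate: float = 0.0077
    entry_cum12_threshold: float = 0.58
    entry_check_max_age_years: int = 38
    diagnosis_min_months_trying: int = 12
    max_age_at_mar_years: Optional[int] = 43  # None = no upper age limit
    min_age_at_mar_years: Optional[int] = None  # None = no lower limit
    max_iui_cycles: int = 6
    max_ivf_icsi_cycles: int = 3
    wait_first_iui_months: int = 1
    wait_between_iui_months: int = 1
    wait_first_ivf_months: int = 1
    wait_between_ivf_months: int = 1
    fet_attempts_per_cycle: int = 1
    postpartum_months: int = 3
    repartner_refractory_months: int = 0

    # month bounds derived from the year thresholds (age at month start)
    def max_mar_month(self) -> int:
        if self.max_age_at_mar_years is None:
            return NEVER
        return (int(self.max_age_at_mar_years) + 1) * 12 - 1  # inclusive last month

    def min_mar_month(self) -> int:
        if self.min_age_at_mar_years is None:
            return AGE_MIN_MONTHS
        return int(self.min_age_at_mar_years) * 12

    def entry_check_max_month(self) -> int:
        return int(self.entry_check_max_age_years) * 12


@dataclass
class Contraception:
    """Contraceptive failure and induced-abortion behaviour.

    ``monthly_failure`` is the monthly probability of an unintended
    conception while contracepting (and not sterile); an unintended pregnancy
    is terminated with ``abortion_probability``.
    """

    monthly_failure: float = 0.005
    abortion_probability: float = 0.5


# ---------------------------------------------------------------------------
# the full parameter set
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    fecundability: FecundabilityModel
    intrauterine_mortality: AgeCurve  # per-pregnancy loss probability by age
    sterility: SterilityModel
    unions: UnionHazards
    education_distribution: dict
    intended_family_size_distribution: dict
    contraception: Contraception
    treatment: TreatmentRates
    multiple_birth: MultipleBirthModel
    uptake: UptakeDistribution
    thresholds: Thresholds = field(default_factory=Thresholds)
    mar_enabled: bool = True
    uptake_share: Optional[float] = None  # lever: replaces per-woman uptake prob
    cohabitation_shift_months: int = 0  # lever: delays the formation schedule

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        errors = []

        def full_span(curve: AgeCurve, name: str):
            if not curve.covers_full_span():
                errors.append(
                    f"curve '{name}' spans [{curve.start}, {curve.stop}] but must "
                    f"cover [{AGE_MIN_MONTHS}, {AGE_MAX_MONTHS}]"
                )

        full_span(self.fecundability.decline, "fecundability.decline")
        full_span(self.intrauterine_mortality, "intrauterine_mortality")
        full_span(self.sterility.cdf, "sterility.cdf")
        if np.any(np.diff(self.sterility.cdf.values) < -1e-12):
            errors.append("sterility CDF must be non-decreasing")
        for edu in EDUCATION_LEVELS:
            for kind, table in (("formation", self.unions.formation), ("dissolution", self.unions.dissolution)):
                if edu not in table:
                    errors.append(f"missing union {kind} hazard for education '{edu}'")
                else:
                    full_span(table[edu], f"unions.{kind}.{edu}")
        for name in TREATMENT_TYPES:
            full_span(self.treatment.curve(name), f"treatment.{name}")
        full_span(self.multiple_birth.natural, "multiple_birth.natural")
        for dist, name in (
            (self.education_distribution, "education_distribution"),
            (self.intended_family_size_distribution, "intended_family_size_distribution"),
        ):
            total = float(sum(dist.values()))
            if abs(total - 1.0) > 1e-9:
                errors.append(f"{name} must sum to 1 (got {total})")
            if any(p < 0 for p in dist.values()):
                errors.append(f"{name} has negative probabilities")
        if set(self.education_distribution) != set(EDUCATION_LEVELS):
            errors.append(f"education_distribution must have levels {EDUCATION_LEVELS}")
        th = self.thresholds
        if not (0 < th.art_fecundability_gate < 1):
            errors.append("art_fecundability_gate must be in (0, 1)")
        if not (0 < th.entry_cum12_threshold < 1):
            errors.append("entry_cum12_threshold must be in (0, 1)")
        if th.max_iui_cycles < 0 or th.max_ivf_icsi_cycles < 0:
            errors.append("cycle limits must be non-negative")
        if self.uptake_share is not None and not (0 <= self.uptake_share <= 1):
            errors.append("uptake_share must be in [0, 1]")
        if self.cohabitation_shift_months < 0:
            errors.append("cohabitation_shift_months must be >= 0")
        if errors:
            raise ParameterValidationError("; ".join(errors))

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# constructors the curve-building pipeline uses
# ---------------------------------------------------------------------------


def cumulative_conception_probability(f, months: int):
    """P(conception within ``months``) under constant monthly probability f.

    Geometric waiting time: 1 - (1 - f)**months.  Used both for the treatment
    entry prognosis check (12-month window) and as a closed-form test oracle.
    """
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("monthly probability must be in [0, 1]")
    if months < 0:
        raise ValueError("months must be non-negative")
    out = 1.0 - (1.0 - f) ** months
    return float(out) if out.ndim == 0 else out


def bootstrap_uptake(mean: float, n: int, draws: int = 10_000, seed: int = 0) -> UptakeDistribution:
    """Nonparametric bootstrap of an uptake proportion.

    Reconstructs a binary pseudo-sample of size ``n`` with ``round(mean * n)``
    successes and resamples it with replacement ``draws`` times, returning the
    resample means.  Resampling a binary vector with k successes is
    distributionally identical to Binomial(n, k/n)/n, which is how the means
    are drawn.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError("mean must be strictly between 0 and 1")
    if n < 2:
        raise ValueError("sample size must be at least 2")
    if draws < 1:
        raise ValueError("draws must be at least 1")
    successes = int(round(mean * n))
    if successes in (0, n):
        raise ValueError("degenerate pseudo-sample: rounded success count is 0 or n")
    rng = np.random.default_rng(seed)
    means = rng.binomial(n, successes / n, size=draws) / n
    return UptakeDistribution(draws=means, source_mean=mean, source_n=n)


def build_multiple_birth_model(
    all_births_curve: AgeCurve,
    mar_birth_fraction_by_age: AgeCurve,
    treatment_means: Mapping[str, float],
    natural_mean: float,
    twin_triplet_counts: tuple,
    treatment_weights: Optional[Mapping[str, float]] = None,
) -> MultipleBirthModel:
    """Derive the natural multiple-birth curve and per-type ratios.

    Register tables of multiple-birth probabilities mix natural and treatment
    deliveries.  The natural curve is recovered by removing, at each age, the
    treatment-attributable excess under a mass-balance argument:

        all(a) = (1 - q(a)) * natural(a) + q(a) * treated_mean
        natural(a) ~= all(a) - q(a) * (treated_mean - natural_mean)

    where q(a) is the treated fraction of births at age a.  Per-type curves
    are the natural curve times ``treatment_mean / natural_mean``.
    """
    if natural_mean <= 0:
        raise ValueError("natural_mean must be positive")
    if any(m < 0 or not math.isfinite(m) for m in treatment_means.values()):
        raise ValueError("treatment means must be finite and non-negative")
    twins, triplets = twin_triplet_counts
    if triplets <= 0 or twins <= 0:
        raise ValueError("twin and triplet counts must be positive")

    if treatment_weights is None:
        treated_mean = float(np.mean(list(treatment_means.values())))
    else:
        w = np.array([treatment_weights[t] for t in treatment_means])
        m = np.array([treatment_means[t] for t in treatment_means])
        treated_mean = float((w * m).sum() / w.sum())

    frac = mar_birth_fraction_by_age.lookup(all_births_curve.ages_months)
    adjusted = all_births_curve.values - frac * (treated_mean - natural_mean)
    if np.any(adjusted < 0):
        log.warning(
            "multiple-birth downward adjustment produced negative values at %d months; clipped to 0",
            int(np.sum(adjusted < 0)),
        )
    natural = AgeCurve(all_births_curve.ages_months, np.clip(adjusted, 0.0, 1.0))
    ratios = {t: m / natural_mean for t, m in treatment_means.items()}
    return MultipleBirthModel(
        natural=natural, ratios=ratios, twin_triplet_ratio=twins / triplets
    )


# ---------------------------------------------------------------------------
# serialisation (directory of YAML + CSV)
# ---------------------------------------------------------------------------

_SCHEMA = "marsim-parameters-v1"


def _write_curve(curve: AgeCurve, path: Path) -> None:
    # %.17g is round-trip exact for float64
    curve.to_frame().to_csv(path, index=False, float_format="%.17g")


def _read_curve(path: Path, context: str) -> AgeCurve:
    if not path.exists():
        raise ParameterValidationError(f"missing curve file '{path.name}' for {context}")
    try:
        return AgeCurve.from_frame(pd.read_csv(path, float_precision="round_trip"))
    except (ValueError, KeyError) as exc:
        raise ParameterValidationError(f"malformed curve table '{path.name}' ({context}): {exc}") from exc


def save_parameters(params: ParameterSet, path) -> None:
    """Write a parameter set as ``parameters.yaml`` plus per-curve CSVs."""
    root = Path(path)
    curves_dir = root / "curves"
    curves_dir.mkdir(parents=True, exist_ok=True)

    def curve_ref(curve: AgeCurve, name: str) -> str:
        _write_curve(curve, curves_dir / f"{name}.csv")
        return f"curves/{name}.csv"

    config = {
        "schema": _SCHEMA,
        "thresholds": {k: v for k, v in asdict(params.thresholds).items()},
        "mar_enabled": params.mar_enabled,
        "uptake_share": params.uptake_share,
        "cohabitation_shift_months": params.cohabitation_shift_months,
        "education_distribution": {k: float(v) for k, v in params.education_distribution.items()},
        "intended_family_size_distribution": {
            int(k): float(v) for k, v in params.intended_family_size_distribution.items()
        },
        "contraception": asdict(params.contraception),
        "fecundability": {
            "beta_a": params.fecundability.beta_a,
            "beta_b": params.fecundability.beta_b,
            "scale": params.fecundability.scale,
            "decline_curve": curve_ref(params.fecundability.decline, "fecundability_decline"),
        },
        "intrauterine_mortality_curve": curve_ref(params.intrauterine_mortality, "intrauterine_mortality"),
        "sterility_cdf_curve": curve_ref(params.sterility.cdf, "sterility_cdf"),
        "unions": {
            "formation": {
                edu: curve_ref(c, f"union_formation_{edu}") for edu, c in params.unions.formation.items()
            },
            "dissolution": {
                edu: curve_ref(c, f"union_dissolution_{edu}") for edu, c in params.unions.dissolution.items()
            },
        },
        "treatment_rates": {
            name.lower(): curve_ref(params.treatment.curve(name), f"treatment_{name.lower()}")
            for name in TREATMENT_TYPES
        },
        "multiple_birth": {
            "natural_curve": curve_ref(params.multiple_birth.natural, "multiple_birth_natural"),
            "ratios": {k: float(v) for k, v in params.multiple_birth.ratios.items()},
            "twin_triplet_ratio": float(params.multiple_birth.twin_triplet_ratio),
        },
        "uptake": {
            "draws_file": "curves/uptake_draws.csv",
            "source_mean": float(params.uptake.source_mean),
            "source_n": int(params.uptake.source_n),
        },
    }
    pd.DataFrame({"probability": params.uptake.draws}).to_csv(
        curves_dir / "uptake_draws.csv", index=False, float_format="%.17g"
    )
    with open(root / "parameters.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def load_parameters(path) -> ParameterSet:
    """Load and validate a parameter set saved by :func:`save_parameters`."""
    root = Path(path)
    config_path = root / "parameters.yaml"
    if not config_path.exists():
        raise ParameterValidationError(f"no parameters.yaml under {root}")
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    if config.get("schema") != _SCHEMA:
        raise ParameterValidationError(f"unknown schema {config.get('schema')!r}; expected {_SCHEMA!r}")

    th_raw = _require(config, "thresholds", "parameters.yaml")
    for key in _REQUIRED_THRESHOLDS:
        if key not in th_raw:
            raise ParameterValidationError(f"missing required field '{key}' in thresholds")
    thresholds = Thresholds(**th_raw)

    fec_raw = _require(config, "fecundability", "parameters.yaml")
    fec = FecundabilityModel(
        beta_a=float(_require(fec_raw, "beta_a", "fecundability")),
        beta_b=float(_require(fec_raw, "beta_b", "fecundability")),
        scale=float(_require(fec_raw, "scale", "fecundability")),
        decline=_read_curve(root / _require(fec_raw, "decline_curve", "fecundability"), "fecundability.decline"),
    )
    unions_raw = _require(config, "unions", "parameters.yaml")
    unions = UnionHazards(
        formation={
            edu: _read_curve(root / ref, f"unions.formation.{edu}")
            for edu, ref in _require(unions_raw, "formation", "unions").items()
        },
        dissolution={
            edu: _read_curve(root / ref, f"unions.dissolution.{edu}")
            for edu, ref in _require(unions_raw, "dissolution", "unions").items()
        },
    )
    tr_raw = _require(config, "treatment_rates", "parameters.yaml")
    treatment = TreatmentRates(
        iui=_read_curve(root / _require(tr_raw, "iui", "treatment_rates"), "treatment.IUI"),
        ivf=_read_curve(root / _require(tr_raw, "ivf", "treatment_rates"), "treatment.IVF"),
        icsi=_read_curve(root / _require(tr_raw, "icsi", "treatment_rates"), "treatment.ICSI"),
        fet=_read_curve(root / _require(tr_raw, "fet", "treatment_rates"), "treatment.FET"),
    )
    mb_raw = _require(config, "multiple_birth", "parameters.yaml")
    multiple_birth = MultipleBirthModel(
        natural=_read_curve(root / _require(mb_raw, "natural_curve", "multiple_birth"), "multiple_birth.natural"),
        ratios={k: float(v) for k, v in _require(mb_raw, "ratios", "multiple_birth").items()},
        twin_triplet_ratio=float(_require(mb_raw, "twin_triplet_ratio", "multiple_birth")),
    )
    up_raw = _require(config, "uptake", "parameters.yaml")
    draws_path = root / _require(up_raw, "draws_file", "uptake")
    if not draws_path.exists():
        raise ParameterValidationError(f"missing uptake draws file '{draws_path.name}'")
    uptake = UptakeDistribution(
        draws=pd.read_csv(draws_path, float_precision="round_trip")["probability"].to_numpy(),
        source_mean=float(_require(up_raw, "source_mean", "uptake")),
        source_n=int(_require(up_raw, "source_n", "uptake")),
    )
    contraception = Contraception(**config.get("contraception", {}))

    params = ParameterSet(
        fecundability=fec,
        intrauterine_mortality=_read_curve(
            root / _require(config, "intrauterine_mortality_curve", "parameters.yaml"), "intrauterine_mortality"
        ),
        sterility=SterilityModel(
            cdf=_read_curve(root / _require(config, "sterility_cdf_curve", "parameters.yaml"), "sterility.cdf")
        ),
        unions=unions,
        education_distribution=_require(config, "education_distribution", "parameters.yaml"),
        intended_family_size_distribution={
            int(k): float(v)
            for k, v in _require(config, "intended_family_size_distribution", "parameters.yaml").items()
        },
        contraception=contraception,
        treatment=treatment,
        multiple_birth=multiple_birth,
        uptake=uptake,
        thresholds=thresholds,
        mar_enabled=bool(config.get("mar_enabled", True)),
        uptake_share=config.get("uptake_share"),
        cohabitation_shift_months=int(config.get("cohabitation_shift_months", 0)),
    )
    params.validate()
    return params
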