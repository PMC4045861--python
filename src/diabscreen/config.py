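"""Scenario configuration for the synthetic survey generators.

A :class:`ScenarioConfig` declares everything the generators need: covariate
marginals (some conditioned on age band and BMI class), the true risk-model
coefficients that drive latent glycemic state, lab-panel assignment rates,
diagnosis rates, visit-count distributions and the sampling-weight
distribution.  Defaults emulate the structure of the US national surveys the
analysis is designed for: an NHANES-style examination survey (lab panel,
diagnosis flags) and a MEPS-style expenditure survey (visit counts, no labs).

Default slopes are the natural logarithms of odds ratios estimated from
NHANES 2003-2010 regressions of glycemic status on these covariates, so that
synthetic populations carry realistic covariate-risk gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass

import numpy as np
import yaml

from .design import (
    AGE_BANDS,
    BMI_CLASSES,
    DESIGN_COLUMNS,
    N_DESIGN,
    RACE_ETH,
    SURVEY_WAVES,
)
from .errors import ConfigError

# Odds ratios (per design column, in DESIGN_COLUMNS order) from the national
# survey regressions: glycemic disorder (undiagnosed diabetes / total
# prediabetes vs normal), diagnosed prediabetes, and diagnosed diabetes.
GLYCEMIA_OR = [
    1.44,
    1.93, 3.70, 5.52, 7.03, 8.89,
    1.61, 1.97, 1.61,
    1.05, 1.02, 1.00, 1.06, 1.03, 1.36, 1.18, 1.18, 1.17,
    1.60, 2.96,
    0.998,
    0.81, 1.17,
    1.42, 2.43, 2.20,
]
DIAG_PREDM_OR = [
    0.80,
    2.01, 2.04, 2.50, 2.43, 1.90,
    1.07, 1.63, 1.08,
    1.51, 1.45, 1.47, 1.07, 1.19, 1.81, 1.56, 1.14, 0.72,
    1.30, 1.92,
    0.998,
    1.16, 1.11,
    2.86, 3.39, 3.79,
]
DIAG_DM_OR = [
    1.16,
    2.09, 4.12, 5.46, 7.10, 5.79,
    1.92, 2.23, 2.22,
    1.10, 1.22, 1.11, 1.82, 1.07, 2.15, 1.90, 1.87, 0.95,
    1.22, 2.79,
    0.994,
    1.22, 1.24,
    0.99, 1.09, 1.04,
]


def _ln(ors) -> np.ndarray:
    return np.log(np.asarray(ors, dtype=float))


@dataclass
class TrueCoefficients:
    """Generating coefficients over the shared design layout.

    ``predm_slopes``/``udm_slopes`` are the two non-reference equations of the
    polytomous model (total prediabetes and undiagnosed diabetes vs normal);
    by default both use the combined glycemic-disorder odds ratios, separated
    only by their intercepts.  Intercepts are chosen so that a scenario with
    default covariate marginals yields roughly 37% prediabetes and 2.5-3%
    undiagnosed diabetes among adults without diagnosed diabetes.
    """

    predm_intercept: float = -2.835
    udm_intercept: float = -5.452
    predm_slopes: np.ndarray = field(default_factory=lambda: _ln(GLYCEMIA_OR))
    udm_slopes: np.ndarray = field(default_factory=lambda: _ln(GLYCEMIA_OR))
    diag_predm_slopes: np.ndarray = field(default_factory=lambda: _ln(DIAG_PREDM_OR))
    diag_dm_slopes: np.ndarray = field(default_factory=lambda: _ln(DIAG_DM_OR))

    def validate(self) -> None:
        for name in ("predm_slopes", "udm_slopes", "diag_predm_slopes", "diag_dm_slopes"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (N_DESIGN,):
                raise ConfigError(
                    f"true_model.{name} must have {N_DESIGN} entries "
                    f"(one per design column {DESIGN_COLUMNS[0]}..{DESIGN_COLUMNS[-1]}), got {v.shape}"
                )
            if not np.isfinite(v).all():
                raise ConfigError(f"true_model.{name} contains non-finite values")
            object.__setattr__(self, name, v)


@dataclass
class ConditionSpec:
    """Log-odds model for one 0/1 condition: base + age_slope*age_idx + bmi_slope*bmi_idx.

    ``age_idx`` runs 0..5 over the age bands, ``bmi_idx`` 0..2 over BMI classes.
    """

    base: float
    age_slope: float = 0.0
    bmi_slope: float = 0.0


@dataclass
class CovariateSpec:
    male_p: float = 0.50
    age_probs: list = field(default_factory=lambda: [0.30, 0.18, 0.18, 0.14, 0.10, 0.10])
    race_probs: list = field(default_factory=lambda: [0.70, 0.11, 0.06, 0.13])
    # BMI class probabilities conditional on age band (rows: AGE_BANDS).
    bmi_probs_by_age: list = field(
        default_factory=lambda: [
            [0.50, 0.28, 0.22],
            [0.40, 0.33, 0.27],
            [0.34, 0.35, 0.31],
            [0.30, 0.35, 0.35],
            [0.30, 0.37, 0.33],
            [0.38, 0.37, 0.25],
        ]
    )
    conditions: dict = field(
        default_factory=lambda: {
            "asthma": ConditionSpec(base=-1.90, age_slope=0.0, bmi_slope=0.10),
            "arthritis": ConditionSpec(base=-3.00, age_slope=0.75, bmi_slope=0.25),
            "heart_attack": ConditionSpec(base=-5.00, age_slope=0.55, bmi_slope=0.10),
            "stroke": ConditionSpec(base=-5.20, age_slope=0.55, bmi_slope=0.05),
            "cancer": ConditionSpec(base=-4.30, age_slope=0.55, bmi_slope=0.0),
            "hypertension": ConditionSpec(base=-2.50, age_slope=0.55, bmi_slope=0.45),
            "high_cholesterol": ConditionSpec(base=-2.60, age_slope=0.55, bmi_slope=0.30),
            "cvd": ConditionSpec(base=-4.80, age_slope=0.60, bmi_slope=0.15),
            "smoker": ConditionSpec(base=-1.20, age_slope=-0.15, bmi_slope=0.0),
        }
    )
    income_median_k: float = 40.0  # thousands of 2010 dollars
    income_sigma: float = 0.80  # log-normal shape
    insured_p: float = 0.78
    medicaid_p: float = 0.06
    wave_probs: list = field(default_factory=lambda: [0.25, 0.25, 0.25, 0.25])
    pregnant_rate_female: float = 0.04

    def validate(self) -> None:
        for name in ("male_p", "insured_p", "medicaid_p", "pregnant_rate_female"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"covariate_spec.{name} must lie in [0,1], got {p}")
        for name, expect in (
            ("age_probs", len(AGE_BANDS)),
            ("race_probs", len(RACE_ETH)),
            ("wave_probs", len(SURVEY_WAVES)),
        ):
            probs = np.asarray(getattr(self, name), dtype=float)
            if probs.shape != (expect,):
                raise ConfigError(f"covariate_spec.{name} must have {expect} entries")
            _check_mixture(f"covariate_spec.{name}", probs)
        bmi = np.asarray(self.bmi_probs_by_age, dtype=float)
        if bmi.shape != (len(AGE_BANDS), len(BMI_CLASSES)):
            raise ConfigError(
                f"covariate_spec.bmi_probs_by_age must be {len(AGE_BANDS)}x{len(BMI_CLASSES)}"
            )
        for i, row in enumerate(bmi):
            _check_mixture(f"covariate_spec.bmi_probs_by_age[{i}]", row)
        if self.income_median_k <= 0 or self.income_sigma < 0:
            raise ConfigError("covariate_spec.income_median_k must be > 0 and income_sigma >= 0")


@dataclass
class LabAssignment:
    """Probability a respondent's lab panel carries each glycemic test."""

    hba1c: float = 1.00
    fpg: float = 0.48
    ogtt: float = 0.31

    def validate(self) -> None:
        for name in ("hba1c", "fpg", "ogtt"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"lab_assignment.{name} must lie in [0,1], got {p}")
        if self.hba1c == 0 and self.fpg == 0 and self.ogtt == 0:
            raise ConfigError("lab_assignment: at least one test probability must be positive")


@dataclass
class DiagnosisSpec:
    """Targets for diagnosis rates; intercepts of the diagnosis models are
    solved at generation time so the realized population hits these means.

    ``diag_dm_rate`` is the overall share of adults carrying a diabetes
    diagnosis; ``diag_predm_rate`` is P(diagnosed | latent prediabetes), i.e.
    1 minus the undetected-prediabetes fraction (~90% undetected by default).
    """

    diag_dm_rate: float = 0.105
    diag_predm_rate: float = 0.10

    def validate(self) -> None:
        for name in ("diag_dm_rate", "diag_predm_rate"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ConfigError(f"diagnosis_spec.{name} must lie in [0,1), got {p}")


@dataclass
class VisitSetting:
    """Poisson visit model for one care setting: mean = base + slope * p_udm.

    ``p_udm`` is the record's true undiagnosed-diabetes probability, so a
    positive slope yields visit counts rising with latent risk.
    """

    base: float
    slope: float = 0.0

    def mean(self, p_udm: np.ndarray) -> np.ndarray:
        return self.base + self.slope * np.asarray(p_udm, dtype=float)


VISIT_SETTINGS = ["primary_care_office", "non_primary_office", "outpatient", "emergency", "inpatient"]


@dataclass
class VisitSpec:
    settings: dict = field(
        default_factory=lambda: {
            "primary_care_office": VisitSetting(base=0.90, slope=12.0),
            "non_primary_office": VisitSetting(base=3.00, slope=28.0),
            "outpatient": VisitSetting(base=0.20, slope=8.0),
            "emergency": VisitSetting(base=0.12, slope=1.0),
            "inpatient": VisitSetting(base=0.04, slope=1.5),
        }
    )
    zero_inflation: float = 0.0  # probability a record has no visits at all

    def validate(self) -> None:
        if set(self.settings) != set(VISIT_SETTINGS):
            raise ConfigError(f"visit_spec.settings must define exactly {VISIT_SETTINGS}")
        for name, s in self.settings.items():
            if s.base < 0:
                raise ConfigError(f"visit_spec.settings.{name}.base must be >= 0")
            if s.base + min(0.0, s.slope) < 0:
                raise ConfigError(f"visit_spec.settings.{name}: mean can go negative over [0,1]")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ConfigError(f"visit_spec.zero_inflation must lie in [0,1], got {self.zero_inflation}")


@dataclass
class WeightSpec:
    """Log-normal sampling weights, independent of covariates."""

    median: float = 10_000.0
    sigma: float = 0.50

    def validate(self) -> None:
        if self.median <= 0:
            raise ConfigError(f"weight_spec.median must be > 0, got {self.median}")
        if self.sigma < 0:
            raise ConfigError(f"weight_spec.sigma must be >= 0, got {self.sigma}")


@dataclass
class ScenarioConfig:
    population_size: int = 20_000
    seed: int = 0
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    true_model: TrueCoefficients = field(default_factory=TrueCoefficients)
    lab_assignment: LabAssignment = field(default_factory=LabAssignment)
    diagnosis_spec: DiagnosisSpec = field(default_factory=DiagnosisSpec)
    visit_spec: VisitSpec = field(default_factory=VisitSpec)
    weight_spec: WeightSpec = field(default_factory=WeightSpec)
    #: probability that a multi-test panel draws one test from a discordant
    #: category; 0 keeps all assigned tests consistent with the latent state.
    discordance_rate: float = 0.0

    def validate(self) -> "ScenarioConfig":
        if int(self.population_size) < 1:
            raise ConfigError(f"population_size must be >= 1, got {self.population_size}")
        if not 0.0 <= self.discordance_rate <= 1.0:
            raise ConfigError(f"discordance_rate must lie in [0,1], got {self.discordance_rate}")
        self.covariate_spec.validate()
        self.true_model.validate()
        self.lab_assignment.validate()
        self.diagnosis_spec.validate()
        self.visit_spec.validate()
        self.weight_spec.validate()
        return self

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_dict(cls, overrides: dict) -> "ScenarioConfig":
        """Build a config from nested dict overrides on top of the defaults."""
        cfg = cls()
        _apply_overrides(cfg, overrides, path="")
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"scenario file {path} must contain a mapping at top level")
        return cls.from_dict(data)


def _check_mixture(name: str, probs: np.ndarray) -> None:
    if (probs < 0).any() or (probs > 1).any():
        raise ConfigError(f"{name} entries must lie in [0,1]")
    if abs(float(probs.sum()) - 1.0) > 1e-9:
        raise ConfigError(f"{name} must sum to 1 (got {probs.sum():.12f})")


def _apply_overrides(obj, overrides: dict, path: str) -> None:
    if not isinstance(overrides, dict):
        raise ConfigError(f"config section '{path or '<root>'}' must be a mapping")
    valid = {f.name: f for f in fields(obj)}
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in valid:
            raise ConfigError(f"unknown config field '{where}'")
        current = getattr(obj, key)
        if is_dataclass(current) and isinstance(value, dict):
            _apply_overrides(current, value, where)
        elif key == "conditions" and isinstance(value, dict):
            merged = dict(current)
            for cname, cval in value.items():
                if isinstance(cval, dict):
                    merged[cname] = ConditionSpec(**cval)
                elif isinstance(cval, ConditionSpec):
                    merged[cname] = cval
                else:
                    raise ConfigError(f"config field '{where}.{cname}' must be a mapping")
            setattr(obj, key, merged)
        elif key == "settings" and isinstance(value, dict):
            merged = dict(current)
            for sname, sval in value.items():
                if sname not in VISIT_SETTINGS:
                    raise ConfigError(f"unknown visit setting '{where}.{sname}'")
                if isinstance(sval, dict):
                    merged[sname] = VisitSetting(**sval)
                elif isinstance(sval, VisitSetting):
                    merged[sname] = sval
                else:
                    raise ConfigError(f"config field '{where}.{sname}' must be a mapping")
            setattr(obj, key, merged)
        else:
            setattr(obj, key, value)
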