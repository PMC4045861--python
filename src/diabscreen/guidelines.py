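"""Screening eligibility rules (ADA, USPSTF, and user-defined).

The ADA guideline screens everyone age 45+ plus overweight/obese adults of
any age with at least one additional risk factor; adults eligible *only*
through age (no excess weight with a risk factor) are re-screened every three
years, modeled as a one-in-three annual screening probability.  The
2008-era USPSTF guideline screens adults with sustained hypertension, proxied
here by the diagnosed-hypertension indicator since the projection survey
carries no measured blood pressure.

The default ADA risk-factor set uses the proxies available in an
expenditure-survey covariate layout: hypertension, high cholesterol,
cardiovascular disease, and high-risk (minority) race/ethnicity.  Family
history, physical inactivity, PCOS, gestational-diabetes history and
acanthosis nigricans are not observable here and are omitted; the set is
overridable per rule instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, MissingDataError

AGE_45_PLUS = {"45-54", "55-64", "65-74", "75+"}
EXCESS_WEIGHT = {"overweight", "obese"}
MINORITY_RACE = {"nh_black", "nh_other", "hispanic"}

#: default ADA "additional risk factor" predicates (name -> frame predicate)
DEFAULT_RISK_FACTORS = {
    "hypertension": lambda f: f["hypertension"].to_numpy(dtype=bool),
    "high_cholesterol": lambda f: f["high_cholesterol"].to_numpy(dtype=bool),
    "cvd": lambda f: f["cvd"].to_numpy(dtype=bool),
    "minority_race": lambda f: f["race_eth"].isin(MINORITY_RACE).to_numpy(),
}


@dataclass
class EligibilityResult:
    """Screening decision for one record."""

    eligible: bool
    fraction: float
    triggered_criteria: list


def _require_columns(frame: pd.DataFrame, columns) -> None:
    for col in columns:
        if col not in frame.columns:
            raise MissingDataError(f"screening rule requires column '{col}'")
        if frame[col].isna().any():
            raise MissingDataError(f"screening rule column '{col}' contains missing values")


class ScreeningRule:
    """A named eligibility predicate with an annual screening fraction.

    Subclasses implement :meth:`evaluate`, returning a frame (aligned with
    the input) with a boolean ``eligible`` column, a float ``fraction``
    column in [0, 1] (zero wherever not eligible), and one boolean
    ``crit_<name>`` column per criterion clause.
    """

    name: str = "rule"

    def evaluate(self, frame: pd.DataFrame) -> pd.DataFrame:  # pragma: no cover
        raise NotImplementedError

    def evaluate_record(self, record) -> EligibilityResult:
        """Scalar convenience wrapper around :meth:`evaluate`."""
        if isinstance(record, pd.Series):
            frame = record.to_frame().T
        elif isinstance(record, dict):
            frame = pd.DataFrame([record])
        else:
            frame = record
        out = self.evaluate(frame)
        row = out.iloc[0]
        triggered = [c[5:] for c in out.columns if c.startswith("crit_") and bool(row[c])]
        return EligibilityResult(bool(row["eligible"]), float(row["fraction"]), triggered)

    def screening_fraction(self, frame: pd.DataFrame, mode: str = "expected", rng=None) -> np.ndarray:
        """Per-record screening fraction.

        ``mode='expected'`` returns the fractional probabilities themselves
        (the default; population totals are expectations).  ``mode='bernoulli'``
        draws a 0/1 screening indicator with those probabilities from ``rng``
        for stochastic sensitivity runs.
        """
        frac = self.evaluate(frame)["fraction"].to_numpy(dtype=float)
        if mode == "expected":
            return frac
        if mode == "bernoulli":
            if rng is None:
                raise ConfigError("bernoulli screening mode requires an rng")
            return (rng.random(len(frac)) < frac).astype(float)
        raise ConfigError(f"unknown screening fraction mode '{mode}'")


class UspstfRule(ScreeningRule):
    """Screen adults with (diagnosed) sustained hypertension; fraction 1."""

    name = "uspstf"

    def evaluate(self, frame: pd.DataFrame) -> pd.DataFrame:
        _require_columns(frame, ["hypertension"])
        htn = frame["hypertension"].to_numpy(dtype=bool)
        return pd.DataFrame(
            {
                "eligible": htn,
                "fraction": htn.astype(float),
                "crit_hypertension": htn,
            },
            index=frame.index,
        )


class AdaRule(ScreeningRule):
    """ADA screening: age 45+ or excess weight with an additional risk factor.

    A record eligible solely through the age clause carries the three-year
    re-screening fraction (1/3 per year); any record satisfying the
    weight-plus-risk-factor clause is screened with fraction 1.
    """

    name = "ada"

    def __init__(self, risk_factors: dict | None = None, low_risk_fraction: float = 1.0 / 3.0):
        self.risk_factors = dict(DEFAULT_RISK_FACTORS if risk_factors is None else risk_factors)
        if not 0.0 <= low_risk_fraction <= 1.0:
            raise ConfigError("low_risk_fraction must lie in [0,1]")
        self.low_risk_fraction = low_risk_fraction

    def evaluate(self, frame: pd.DataFrame) -> pd.DataFrame:
        _require_columns(frame, ["age_band", "bmi_class"])
        age_45 = frame["age_band"].isin(AGE_45_PLUS).to_numpy()
        excess = frame["bmi_class"].isin(EXCESS_WEIGHT).to_numpy()
        any_rf = np.zeros(len(frame), dtype=bool)
        out = pd.DataFrame(index=frame.index)
        for rf_name, pred in self.risk_factors.items():
            try:
                hit = np.asarray(pred(frame), dtype=bool)
            except KeyError as exc:
                raise MissingDataError(f"risk factor '{rf_name}' needs column {exc}") from exc
            any_rf |= hit
        weight_clause = excess & any_rf
        eligible = age_45 | weight_clause
        fraction = np.where(weight_clause, 1.0, np.where(age_45, self.low_risk_fraction, 0.0))
        out["eligible"] = eligible
        out["fraction"] = fraction
        out["crit_age_45_plus"] = age_45
        out["crit_weight_plus_risk_factor"] = weight_clause
        return out


def uspstf_eligible(record) -> EligibilityResult:
    return UspstfRule().evaluate_record(record)


def ada_eligible(record, risk_factors: dict | None = None) -> EligibilityResult:
    return AdaRule(risk_factors).evaluate_record(record)


BUILTIN_RULES = {"ada": AdaRule, "uspstf": UspstfRule}


def get_rule(name: str, **kwargs) -> ScreeningRule:
    try:
        return BUILTIN_RULES[name](**kwargs)
    except KeyError:
        raise ConfigError(f"unknown screening rule '{name}'") from None


def rule_from_config(spec: dict) -> ScreeningRule:
    """Build a simple declarative rule from a config mapping.

    Schema::

        name: my_rule
        fraction: 1.0            # applied to every eligible record
        any_of:                  # eligible iff any clause holds
          - {column: hypertension, equals: 1}
          - {column: age_band, in: ["65-74", "75+"]}
    """
    name = spec.get("name", "custom")
    fraction = float(spec.get("fraction", 1.0))
    clauses = spec.get("any_of", [])
    if not clauses:
        raise ConfigError("rule config needs a non-empty 'any_of' clause list")

    class _ConfigRule(ScreeningRule):
        def evaluate(self, frame: pd.DataFrame) -> pd.DataFrame:
            out = pd.DataFrame(index=frame.index)
            eligible = np.zeros(len(frame), dtype=bool)
            for i, clause in enumerate(clauses):
                col = clause.get("column")
                _require_columns(frame, [col])
                if "equals" in clause:
                    hit = (frame[col] == clause["equals"]).to_numpy()
                elif "in" in clause:
                    hit = frame[col].isin(clause["in"]).to_numpy()
                else:
                    raise ConfigError(f"clause {i} of rule '{name}' needs 'equals' or 'in'")
                out[f"crit_{col}_{i}"] = hit
                eligible |= hit
            out["eligible"] = eligible
            out["fraction"] = eligible.astype(float) * fraction
            return out

    rule = _ConfigRule()
    rule.name = name
    return rule


def rule_overlap(frame: pd.DataFrame, rule_a: ScreeningRule, rule_b: ScreeningRule) -> pd.DataFrame:
    """Partition records by joint eligibility under two rules.

    Returns one row per cell (``both``, ``a_only``, ``b_only``, ``neither``)
    with record counts, plain-weight population totals (eligibility
    accounting), and fraction-weighted screened totals per rule (screened-
    population accounting).
    """
    ev_a = rule_a.evaluate(frame)
    ev_b = rule_b.evaluate(frame)
    w = frame["weight"].to_numpy(dtype=float)
    a = ev_a["eligible"].to_numpy()
    b = ev_b["eligible"].to_numpy()
    fa = ev_a["fraction"].to_numpy(dtype=float)
    fb = ev_b["fraction"].to_numpy(dtype=float)

    cells = {
        "both": a & b,
        "a_only": a & ~b,
        "b_only": ~a & b,
        "neither": ~a & ~b,
    }
    rows = []
    for cell, mask in cells.items():
        rows.append(
            {
                "cell": cell,
                "n_records": int(mask.sum()),
                "population": float(w[mask].sum()),
                "screened_a": float((w * fa)[mask].sum()),
                "screened_b": float((w * fb)[mask].sum()),
            }
        )
    return pd.DataFrame(rows).set_index("cell")
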