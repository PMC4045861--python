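"""Expected screened and detected population counts under a screening rule.

Each survey record represents ``weight`` persons.  If it is eligible with
annual screening fraction ``f``, it contributes ``weight * f`` persons
screened, ``weight * f * scale * p_undiag_dm`` persons detected with diabetes
and ``weight * f * scale * p_undet_predm`` persons detected with prediabetes,
where ``scale`` is the national-total calibration factor.  Detected counts
are expectations (probability sums) and are never integerized; rounding
happens only at the presentation layer, half away from zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError
from .guidelines import ScreeningRule, rule_overlap


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def screened_per_case(screened: float, detected: float, ndigits: int | None = None) -> float:
    """People screened per case detected; optionally presentation-rounded."""
    ratio = screened / detected
    return ratio if ndigits is None else round_half_away(ratio, ndigits)


def percent_more(value_a: float, value_b: float, ndigits: int | None = None) -> float:
    """Percent by which ``value_a`` exceeds ``value_b`` (ratio minus one)."""
    pct = (value_a / value_b - 1.0) * 100.0
    return pct if ndigits is None else round_half_away(pct, ndigits)


def coverage_percent(detected: float, national_total: float, ndigits: int | None = None) -> float:
    """Detected cases as a percent of the national total of the condition."""
    pct = detected / national_total * 100.0
    return pct if ndigits is None else round_half_away(pct, ndigits)


@dataclass
class ProjectionResult:
    """Population totals (persons) from one screening rule."""

    screened_total: float
    detected_dm: float
    detected_predm: float
    screened_per_dm_case: float
    screened_per_any_case: float
    by_subgroup: pd.DataFrame | None = None

    def as_thousands(self) -> dict:
        return {
            "screened_total": round_half_away(self.screened_total / 1e3),
            "detected_dm": round_half_away(self.detected_dm / 1e3),
            "detected_predm": round_half_away(self.detected_predm / 1e3),
        }


def _aligned_arrays(frame: pd.DataFrame, profiles: pd.DataFrame):
    if len(frame) != len(profiles) or not frame.index.equals(profiles.index):
        raise SchemaError("risk profiles are not aligned with the survey frame")
    for col in ("p_undiag_dm", "p_undet_predm"):
        if col not in profiles.columns:
            raise SchemaError(f"profiles frame lacks column '{col}'")
    return (
        frame["weight"].to_numpy(dtype=float),
        profiles["p_undiag_dm"].to_numpy(dtype=float),
        profiles["p_undet_predm"].to_numpy(dtype=float),
    )


def _totals(w, frac, p_dm, p_pd, scale):
    screened = float((w * frac).sum())
    dm = float((w * frac * p_dm).sum()) * scale
    pd_ = float((w * frac * p_pd).sum()) * scale
    return screened, dm, pd_


def _ratios(screened, dm, pd_):
    if dm <= 0 or dm + pd_ <= 0:
        warnings.warn("no detectable cases under this rule; ratios undefined", stacklevel=3)
        return float("nan"), float("nan")
    return screened / dm, screened / (dm + pd_)


def project(
    frame: pd.DataFrame,
    profiles: pd.DataFrame,
    rule: ScreeningRule,
    scale: float = 1.0,
    fraction_mode: str = "expected",
    rng=None,
) -> ProjectionResult:
    """Expected screened/detected totals for one rule over a projection survey."""
    if scale <= 0:
        raise SchemaError(f"scale must be positive, got {scale}")
    w, p_dm, p_pd = _aligned_arrays(frame, profiles)
    frac = rule.screening_fraction(frame, mode=fraction_mode, rng=rng)
    screened, dm, pd_ = _totals(w, frac, p_dm, p_pd, scale)
    r_dm, r_any = _ratios(screened, dm, pd_)
    return ProjectionResult(screened, dm, pd_, r_dm, r_any)


# ---------------------------------------------------------------------------
# Subgroup tables
# ---------------------------------------------------------------------------

#: collapsed age bands used by the report tables
AGE4_LEVELS = ["<45", "45-54", "55-64", "65+"]


def _age4(frame: pd.DataFrame) -> pd.Series:
    mapping = {
        "18-34": "<45",
        "35-44": "<45",
        "45-54": "45-54",
        "55-64": "55-64",
        "65-74": "65+",
        "75+": "65+",
    }
    return frame["age_band"].map(mapping)


def _weighted_quartile(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    cum = np.cumsum(weights[order])
    cum = cum / cum[-1]
    q = np.searchsorted(np.array([0.25, 0.5, 0.75]), cum, side="left")
    out = np.empty(len(values), dtype=int)
    out[order] = np.clip(q, 0, 3)
    return out


def subgroup_labels(frame: pd.DataFrame, grouping: str) -> pd.Series:
    """Per-record subgroup label for a named grouping."""
    if grouping == "age":
        return _age4(frame)
    if grouping == "sex":
        return frame["male"].map({1: "men", 0: "women"})
    if grouping == "race":
        return frame["race_eth"]
    if grouping == "bmi":
        return frame["bmi_class"]
    if grouping == "insured":
        return frame["insured"].map({1: "insured", 0: "uninsured"})
    if grouping == "income_quartile":
        q = _weighted_quartile(
            frame["income_k"].to_numpy(dtype=float), frame["weight"].to_numpy(dtype=float)
        )
        return pd.Series(q, index=frame.index).map(
            {0: "first", 1: "second", 2: "third", 3: "fourth"}
        )
    raise SchemaError(f"unknown grouping '{grouping}'")


GROUPINGS = ["age", "sex", "race", "bmi", "income_quartile", "insured"]


def subgroup_table(
    frame: pd.DataFrame,
    profiles: pd.DataFrame,
    rule: ScreeningRule,
    grouping: str,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Screened/detected totals by level of one grouping (rows sum to totals)."""
    w, p_dm, p_pd = _aligned_arrays(frame, profiles)
    frac = rule.screening_fraction(frame)
    labels = subgroup_labels(frame, grouping)
    df = pd.DataFrame(
        {
            "screened": w * frac,
            "detected_dm": w * frac * p_dm * scale,
            "detected_predm": w * frac * p_pd * scale,
            "_label": labels.to_numpy(),
        },
        index=frame.index,
    )
    out = df.groupby("_label", sort=True).sum()
    out.index.name = grouping
    return out


# ---------------------------------------------------------------------------
# Rule comparison
# ---------------------------------------------------------------------------


@dataclass
class RuleComparison:
    """Side-by-side totals for two rules plus their eligibility overlap."""

    result_a: ProjectionResult
    result_b: ProjectionResult
    name_a: str
    name_b: str
    overlap: pd.DataFrame
    pct_more_dm: float
    pct_more_predm: float


def compare_rules(
    frame: pd.DataFrame,
    profiles: pd.DataFrame,
    rule_a: ScreeningRule,
    rule_b: ScreeningRule,
    scale: float = 1.0,
) -> RuleComparison:
    """Compare two screening rules on the same projection survey.

    The overlap partition carries, per cell, each rule's fraction-weighted
    screened and detected totals; percent-more statistics are computed from
    the unrounded totals.
    """
    res_a = project(frame, profiles, rule_a, scale)
    res_b = project(frame, profiles, rule_b, scale)
    overlap = rule_overlap(frame, rule_a, rule_b)

    w, p_dm, p_pd = _aligned_arrays(frame, profiles)
    ev_a = rule_a.evaluate(frame)
    ev_b = rule_b.evaluate(frame)
    a = ev_a["eligible"].to_numpy()
    b = ev_b["eligible"].to_numpy()
    fa = ev_a["fraction"].to_numpy(dtype=float)
    fb = ev_b["fraction"].to_numpy(dtype=float)
    masks = {"both": a & b, "a_only": a & ~b, "b_only": ~a & b, "neither": ~a & ~b}
    for col, vec in (
        ("detected_dm_a", w * fa * p_dm * scale),
        ("detected_predm_a", w * fa * p_pd * scale),
        ("detected_dm_b", w * fb * p_dm * scale),
        ("detected_predm_b", w * fb * p_pd * scale),
    ):
        overlap[col] = [float(vec[m].sum()) for m in masks.values()]

    return RuleComparison(
        result_a=res_a,
        result_b=res_b,
        name_a=rule_a.name,
        name_b=rule_b.name,
        overlap=overlap,
        pct_more_dm=percent_more(res_a.detected_dm, res_b.detected_dm),
        pct_more_predm=percent_more(res_a.detected_predm, res_b.detected_predm),
    )
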