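"""Health-care visit patterns by predicted-risk band and screening opportunities.

Visit-pattern tables stratify a projection survey into half-open bands of a
predicted probability (e.g. undiagnosed-diabetes risk bands <0.05,
0.05 to <0.10, >=0.10) and report the weighted population and weighted mean
annual visit counts per care setting.  The primary-care opportunity report
quantifies how many rule-eligible people had at least one primary care office
visit during the year — the realistic channel for opportunistic screening —
and what share of the rule's detectable cases they carry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, MissingDataError, SchemaError
from .guidelines import ScreeningRule
from .projection import _aligned_arrays, round_half_away
from .synthetic import VISIT_COLUMNS


@dataclass
class RiskBandSpec:
    """Half-open bands [lo, hi) of one predicted-probability column."""

    variable: str = "p_undiag_dm"
    breakpoints: tuple = (0.05, 0.10)

    def validate(self) -> "RiskBandSpec":
        if self.variable not in ("p_undiag_dm", "p_undet_predm"):
            raise ConfigError(f"risk band variable must be a predicted probability, got '{self.variable}'")
        bp = np.asarray(self.breakpoints, dtype=float)
        if len(bp) and (np.diff(bp) <= 0).any():
            raise ConfigError("breakpoints must be strictly ascending")
        if len(bp) and ((bp <= 0).any() or (bp >= 1).any()):
            raise ConfigError("breakpoints must lie strictly inside (0,1)")
        return self

    def labels(self) -> list:
        bp = list(self.breakpoints)
        if not bp:
            return ["all"]
        labels = [f"<{bp[0]:g}"]
        labels += [f"{lo:g} to <{hi:g}" for lo, hi in zip(bp[:-1], bp[1:])]
        labels.append(f">={bp[-1]:g}")
        return labels

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Band index per value (last band closed above at 1)."""
        return np.searchsorted(np.asarray(self.breakpoints, dtype=float), values, side="right")


def _visit_arrays(frame: pd.DataFrame) -> dict:
    out = {}
    for col in VISIT_COLUMNS:
        if col not in frame.columns:
            raise MissingDataError(f"projection survey lacks visit column '{col}'")
        v = frame[col].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise MissingDataError(f"visit column '{col}' contains missing values")
        out[col] = v
    return out


def utilization_by_band(
    frame: pd.DataFrame, profiles: pd.DataFrame, spec: RiskBandSpec
) -> pd.DataFrame:
    """Weighted population and mean annual visits per risk band.

    Each record falls in exactly one band of its predicted probability;
    means are sampling-weighted.  The ``total`` column is the sum of the five
    setting means.
    """
    spec.validate()
    if spec.variable not in profiles.columns:
        raise SchemaError(f"profiles lack column '{spec.variable}'")
    if not frame.index.equals(profiles.index):
        raise SchemaError("risk profiles are not aligned with the survey frame")
    visits = _visit_arrays(frame)
    w = frame["weight"].to_numpy(dtype=float)
    band = spec.assign(profiles[spec.variable].to_numpy(dtype=float))
    labels = spec.labels()

    rows = []
    for i, label in enumerate(labels):
        mask = band == i
        pop = float(w[mask].sum())
        row = {"band": label, "population": pop}
        total = 0.0
        for col, v in visits.items():
            mean = float((w[mask] * v[mask]).sum() / pop) if pop > 0 else float("nan")
            row[f"mean_{col}"] = mean
            total += mean if pop > 0 else 0.0
        row["mean_total"] = total if pop > 0 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("band")


@dataclass
class OpportunityReport:
    """Screening opportunities during primary care office visits, one rule."""

    rule: str
    screened_total: float
    with_primary_care: float  # fraction-weighted persons with >=1 PC visit
    pct_with_primary_care: float
    detectable_dm_total: float
    detectable_predm_total: float
    detectable_dm_primary_care: float
    detectable_predm_primary_care: float
    pct_dm_reachable: float
    pct_predm_reachable: float


def percent_of(part: float, whole: float, ndigits: int | None = None) -> float:
    pct = part / whole * 100.0
    return pct if ndigits is None else round_half_away(pct, ndigits)


def primary_care_opportunity(
    frame: pd.DataFrame,
    profiles: pd.DataFrame,
    rule: ScreeningRule,
    scale: float = 1.0,
) -> OpportunityReport:
    """How much of a rule's detectable caseload is reachable in primary care.

    "At least one primary care visit" uses the primary-care office setting
    only; hospital outpatient visits do not count.  All totals are
    fraction-weighted so they are comparable with the rule's projection
    totals, of which they are subsets.
    """
    w, p_dm, p_pd = _aligned_arrays(frame, profiles)
    visits = _visit_arrays(frame)
    frac = rule.screening_fraction(frame)
    has_pc = visits["visits_primary_care_office"] >= 1

    wf = w * frac
    screened = float(wf.sum())
    with_pc = float(wf[has_pc].sum())
    dm_total = float((wf * p_dm).sum()) * scale
    pd_total = float((wf * p_pd).sum()) * scale
    dm_pc = float((wf * p_dm)[has_pc].sum()) * scale
    pd_pc = float((wf * p_pd)[has_pc].sum()) * scale

    return OpportunityReport(
        rule=rule.name,
        screened_total=screened,
        with_primary_care=with_pc,
        pct_with_primary_care=percent_of(with_pc, screened) if screened > 0 else float("nan"),
        detectable_dm_total=dm_total,
        detectable_predm_total=pd_total,
        detectable_dm_primary_care=dm_pc,
        detectable_predm_primary_care=pd_pc,
        pct_dm_reachable=percent_of(dm_pc, dm_total) if dm_total > 0 else float("nan"),
        pct_predm_reachable=percent_of(pd_pc, pd_total) if pd_total > 0 else float("nan"),
    )
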