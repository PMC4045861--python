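"""Glycemic status assignment from lab panels and diagnosis flags.

Diabetes is defined as any assigned test in the diabetes range (HbA1c >= 6.5%,
FPG >= 126 mg/dL, or 2-h OGTT >= 200 mg/dL); prediabetes as any assigned test
in the prediabetes range (HbA1c 5.7-6.4, FPG 100-125, OGTT 140-199) with no
test in the diabetes range; otherwise normal.  Printed integer bounds leave
e.g. FPG in (125, 126) unassigned, so ranges are implemented half-open and
anchored at the diabetes cutoffs: prediabetes FPG is [100, 126).

A self-reported diabetes diagnosis dominates lab values.  Among undiagnosed
adults the lab category is crossed with the prediabetes-diagnosis flag to give
the modeling categories: normal, undetected prediabetes, diagnosed
prediabetes, undiagnosed diabetes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError

# Lab categories
NORMAL = "normal"
PREDIABETES = "prediabetes"
DIABETES = "diabetes"

# Person-level statuses
UNDETECTED_PREDIABETES = "undetected_prediabetes"
DIAGNOSED_PREDIABETES = "diagnosed_prediabetes"
UNDIAGNOSED_DIABETES = "undiagnosed_diabetes"
DIAGNOSED_DIABETES = "diagnosed_diabetes"

STATUSES = [NORMAL, UNDETECTED_PREDIABETES, DIAGNOSED_PREDIABETES, UNDIAGNOSED_DIABETES, DIAGNOSED_DIABETES]

ALL_TESTS = ("hba1c", "fpg", "ogtt")

#: lower bound of the diabetes range per test
DIABETES_CUTOFF = {"hba1c": 6.5, "fpg": 126.0, "ogtt": 200.0}
#: lower bound of the prediabetes range per test
PREDIABETES_CUTOFF = {"hba1c": 5.7, "fpg": 100.0, "ogtt": 140.0}

#: survey-frame column per test name
TEST_COLUMNS = {"hba1c": "hba1c", "fpg": "fpg", "ogtt": "ogtt_2h"}


@dataclass(frozen=True)
class LabPanel:
    """Up to three glycemic test values; ``None`` marks a test not performed."""

    hba1c: float | None = None
    fpg: float | None = None
    ogtt_2h: float | None = None

    def value(self, test: str) -> float | None:
        return {"hba1c": self.hba1c, "fpg": self.fpg, "ogtt": self.ogtt_2h}[test]


def _normalize_subset(subset) -> tuple:
    tests = tuple(subset) if subset is not None else ALL_TESTS
    unknown = set(tests) - set(ALL_TESTS)
    if unknown:
        raise MissingDataError(f"unknown test names: {sorted(unknown)}")
    if not tests:
        raise MissingDataError("test subset must be non-empty")
    return tests


def classify_lab(panel: LabPanel, subset=None) -> str:
    """Classify one lab panel as diabetes / prediabetes / normal.

    Only tests in ``subset`` (default: all three) are consulted; a panel with
    no value among the included tests raises :class:`MissingDataError`.
    """
    tests = _normalize_subset(subset)
    values = {t: panel.value(t) for t in tests if panel.value(t) is not None and not pd.isna(panel.value(t))}
    if not values:
        raise MissingDataError(f"no lab value present among included tests {tests}")
    if any(v >= DIABETES_CUTOFF[t] for t, v in values.items()):
        return DIABETES
    if any(v >= PREDIABETES_CUTOFF[t] for t, v in values.items()):
        return PREDIABETES
    return NORMAL


def assign_status(
    panel: LabPanel | None,
    diagnosed_diabetes: bool,
    diagnosed_prediabetes: bool = False,
    subset=None,
) -> str:
    """Place a respondent into one of the five glycemic status categories.

    The diabetes-diagnosis flag dominates; otherwise the lab category decides,
    with lab prediabetes split by the prediabetes-diagnosis flag.  A lab value
    in the diabetes range overrides a prediabetes diagnosis (the respondent's
    diabetes is still undiagnosed).
    """
    if diagnosed_diabetes:
        return DIAGNOSED_DIABETES
    if panel is None:
        raise MissingDataError("record has neither a lab panel nor a diabetes diagnosis")
    lab = classify_lab(panel, subset)
    if lab == DIABETES:
        return UNDIAGNOSED_DIABETES
    if lab == PREDIABETES:
        return DIAGNOSED_PREDIABETES if diagnosed_prediabetes else UNDETECTED_PREDIABETES
    return NORMAL


def classify_frame(frame: pd.DataFrame, subset=None, column: str = "status") -> pd.DataFrame:
    """Vectorized :func:`assign_status` over a model-survey frame.

    Returns a copy with ``column`` appended.  Rows with a diabetes diagnosis
    need no lab values; any other row must carry at least one included test.
    """
    tests = _normalize_subset(subset)
    n = len(frame)
    diag_dm = frame["diagnosed_diabetes"].to_numpy(dtype=bool)
    diag_pd = (
        frame["diagnosed_prediabetes"].to_numpy(dtype=bool)
        if "diagnosed_prediabetes" in frame.columns
        else np.zeros(n, dtype=bool)
    )

    any_dm = np.zeros(n, dtype=bool)
    any_pd = np.zeros(n, dtype=bool)
    any_value = np.zeros(n, dtype=bool)
    for t in tests:
        col = TEST_COLUMNS[t]
        if col not in frame.columns:
            continue
        v = frame[col].to_numpy(dtype=float)
        present = ~np.isnan(v)
        any_value |= present
        any_dm |= present & (v >= DIABETES_CUTOFF[t])
        any_pd |= present & (v >= PREDIABETES_CUTOFF[t])

    missing = ~diag_dm & ~any_value
    if missing.any():
        raise MissingDataError(
            f"{int(missing.sum())} undiagnosed records have no lab value among included tests {tests}"
        )

    status = np.full(n, NORMAL, dtype=object)
    status[any_pd & ~any_dm & ~diag_pd] = UNDETECTED_PREDIABETES
    status[any_pd & ~any_dm & diag_pd] = DIAGNOSED_PREDIABETES
    status[any_dm] = UNDIAGNOSED_DIABETES
    status[diag_dm] = DIAGNOSED_DIABETES

    out = frame.copy()
    out[column] = status
    return out


def apply_exclusions(frame: pd.DataFrame):
    """Drop pregnant respondents and those with diagnosed diabetes.

    Returns ``(kept, n_pregnant, n_diagnosed_dm)`` with input order preserved.
    A record that is both pregnant and diagnosed is counted once, attributed
    to pregnancy (fixed attribution order for reproducible logs).
    """
    pregnant = (
        frame["pregnant"].to_numpy(dtype=bool)
        if "pregnant" in frame.columns
        else np.zeros(len(frame), dtype=bool)
    )
    diag_dm = frame["diagnosed_diabetes"].to_numpy(dtype=bool)
    n_pregnant = int(pregnant.sum())
    n_diag_dm = int((diag_dm & ~pregnant).sum())
    kept = frame.loc[~pregnant & ~diag_dm].copy()
    return kept, n_pregnant, n_diag_dm


#: model outcome coding for the polytomous fit (reference first)
OUTCOME_LEVELS = [NORMAL, PREDIABETES, DIABETES]


def collapse_status(status: pd.Series) -> np.ndarray:
    """Collapse five-way status to the 3-category model outcome.

    Normal -> 0; prediabetes (diagnosed or undetected) -> 1; undiagnosed
    diabetes -> 2.  Diagnosed-diabetes rows must be excluded beforehand.
    """
    s = np.asarray(status, dtype=object)
    if (s == DIAGNOSED_DIABETES).any():
        raise MissingDataError("diagnosed-diabetes records must be excluded before model fitting")
    out = np.zeros(len(s), dtype=int)
    out[(s == UNDETECTED_PREDIABETES) | (s == DIAGNOSED_PREDIABETES)] = 1
    out[s == UNDIAGNOSED_DIABETES] = 2
    return out
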