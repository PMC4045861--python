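"""Shared covariate layout for the risk regressions.

Every stage of the pipeline (simulation, model fitting, projection) works on
survey frames that carry the same covariates: dichotomous indicators for sex,
chronic conditions, insurance and smoking; indicator blocks for age band,
race/ethnicity, BMI class and survey wave; and family income measured
continuously in thousands of 2010 dollars.  This module owns the canonical
column order of the regression design matrix, so that coefficient vectors are
interchangeable between the generator, the fitters and the predictors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError

# Categorical levels; the first level of each block is the reference and gets
# no indicator column in the design matrix.
AGE_BANDS = ["18-34", "35-44", "45-54", "55-64", "65-74", "75+"]
RACE_ETH = ["nh_white", "nh_black", "nh_other", "hispanic"]
BMI_CLASSES = ["normal", "overweight", "obese"]
SURVEY_WAVES = ["2003-4", "2005-6", "2007-8", "2009-10"]

#: 0/1 covariates carried by every survey record (besides the blocks above).
BINARY_COVARIATES = [
    "male",
    "asthma",
    "arthritis",
    "heart_attack",
    "stroke",
    "cancer",
    "hypertension",
    "high_cholesterol",
    "cvd",
    "smoker",
    "insured",
    "medicaid",
]

#: Columns a survey frame must provide to build a design matrix.
COVARIATE_COLUMNS = BINARY_COVARIATES + ["age_band", "race_eth", "bmi_class", "income_k", "survey_wave"]

#: Design-matrix columns, in the fixed order used by every coefficient vector.
DESIGN_COLUMNS = (
    ["male"]
    + [f"age_{b.replace('-', '_').replace('+', 'p')}" for b in AGE_BANDS[1:]]
    + RACE_ETH[1:]
    + [
        "asthma",
        "arthritis",
        "heart_attack",
        "stroke",
        "cancer",
        "hypertension",
        "high_cholesterol",
        "cvd",
        "smoker",
    ]
    + BMI_CLASSES[1:]
    + ["income_k"]
    + ["insured", "medicaid"]
    + [f"wave_{w.replace('-', '_')}" for w in SURVEY_WAVES[1:]]
)

N_DESIGN = len(DESIGN_COLUMNS)  # 26

# Map design column -> (frame column, level) for indicator-block members.
_BLOCK_MEMBERS = {}
for _band, _col in zip(AGE_BANDS[1:], DESIGN_COLUMNS[1:6]):
    _BLOCK_MEMBERS[_col] = ("age_band", _band)
for _lvl in RACE_ETH[1:]:
    _BLOCK_MEMBERS[_lvl] = ("race_eth", _lvl)
for _lvl in BMI_CLASSES[1:]:
    _BLOCK_MEMBERS[_lvl] = ("bmi_class", _lvl)
for _wave, _col in zip(SURVEY_WAVES[1:], DESIGN_COLUMNS[-3:]):
    _BLOCK_MEMBERS[_col] = ("survey_wave", _wave)

#: design column -> categorical frame column it indicates, for block handling
BLOCK_OF = {c: frame_col for c, (frame_col, _) in _BLOCK_MEMBERS.items()}


def design_matrix(frame: pd.DataFrame) -> np.ndarray:
    """Build the (n, 26) design matrix from a survey frame.

    Categorical blocks are expanded to reference-coded indicators; the
    intercept is *not* included (fitters append it themselves).

    Raises
    ------
    SchemaError
        if a required covariate column is absent or a categorical column
        contains an unknown level.
    """
    missing = [c for c in COVARIATE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"survey frame lacks covariate columns: {missing}")
    for col, levels in [
        ("age_band", AGE_BANDS),
        ("race_eth", RACE_ETH),
        ("bmi_class", BMI_CLASSES),
        ("survey_wave", SURVEY_WAVES),
    ]:
        bad = set(frame[col].unique()) - set(levels)
        if bad:
            raise SchemaError(f"unknown {col} levels: {sorted(bad)}")

    n = len(frame)
    X = np.empty((n, N_DESIGN), dtype=float)
    for j, name in enumerate(DESIGN_COLUMNS):
        if name == "income_k":
            X[:, j] = frame["income_k"].to_numpy(dtype=float)
        elif name in _BLOCK_MEMBERS:
            frame_col, level = _BLOCK_MEMBERS[name]
            X[:, j] = (frame[frame_col] == level).to_numpy(dtype=float)
        else:
            X[:, j] = frame[name].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise SchemaError("design matrix contains non-finite covariate values")
    return X


def weighted_mean_design(frame: pd.DataFrame, weights: np.ndarray | None = None) -> np.ndarray:
    """Population-average design vector (weighted mean of each column)."""
    X = design_matrix(frame)
    if weights is None:
        weights = frame["weight"].to_numpy(dtype=float)
    w = np.asarray(weights, dtype=float)
    return (X * w[:, None]).sum(axis=0) / w.sum()
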