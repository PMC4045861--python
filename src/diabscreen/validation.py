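"""Split-sample validation of the predictive model.

The classified model survey is randomly divided into two halves; the risk
model is fitted on the first half and applied to the held-out half, where
summed predicted probabilities are compared with observed weighted category
counts by age band.  Fitting the model on each half separately also yields a
coefficient-similarity summary (max and mean absolute difference), since
"similar coefficients across halves" is the informal stability criterion of
this design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import DIAGNOSED_PREDIABETES, UNDETECTED_PREDIABETES, UNDIAGNOSED_DIABETES
from .design import AGE_BANDS
from .errors import DegenerateDataError
from .risk_models import FittedRiskModel, fit_risk_models, predict_risk


def split_half(frame: pd.DataFrame, seed: int, stratify=None):
    """Seeded exact half split; odd n puts the extra record in the first half.

    ``stratify`` may name a column; the split is then performed within each
    of its levels (approximately preserving level shares in both halves).
    """
    rng = np.random.default_rng(int(seed))
    n = len(frame)
    if stratify is None:
        perm = rng.permutation(n)
        n_a = (n + 1) // 2
        idx_a, idx_b = perm[:n_a], perm[n_a:]
    else:
        parts_a, parts_b = [], []
        for _, grp in frame.groupby(stratify, sort=True):
            loc = frame.index.get_indexer(grp.index)
            perm = rng.permutation(len(loc))
            k = (len(loc) + 1) // 2
            parts_a.append(loc[perm[:k]])
            parts_b.append(loc[perm[k:]])
        idx_a = np.concatenate(parts_a)
        idx_b = np.concatenate(parts_b)
    return frame.iloc[np.sort(idx_a)], frame.iloc[np.sort(idx_b)]


@dataclass
class ValidationReport:
    """Predicted-vs-observed holdout totals and half-fit coefficient stability."""

    by_age: pd.DataFrame
    n_fit: int
    n_holdout: int
    max_abs_coef_diff: float
    mean_abs_coef_diff: float
    model_fit: FittedRiskModel
    model_holdout: FittedRiskModel


def _check_halves(half: pd.DataFrame, status_col: str, which: str) -> None:
    s = half[status_col]
    n_predm = int(s.isin([UNDETECTED_PREDIABETES, DIAGNOSED_PREDIABETES]).sum())
    n_udm = int((s == UNDIAGNOSED_DIABETES).sum())
    if n_predm < 2 or n_udm < 2:
        raise DegenerateDataError(
            f"{which} half has too few outcome cases (prediabetes={n_predm}, undiagnosed dm={n_udm})"
        )


def split_sample_validate(
    frame: pd.DataFrame,
    seed: int,
    status_col: str = "status",
    weight_col: str = "weight",
    stratified: bool = False,
) -> ValidationReport:
    """Fit on a random half, predict the other, compare by age band.

    ``frame`` must be the classified, post-exclusion model survey (no
    diagnosed-diabetes records).  The report carries, per age band, the
    holdout's observed weighted counts of prediabetes (any) and undiagnosed
    diabetes, the summed predicted probabilities from the first-half model,
    and their predicted/observed ratios.
    """
    half_a, half_b = split_half(frame, seed, stratify=status_col if stratified else None)
    _check_halves(half_a, status_col, "fit")
    _check_halves(half_b, status_col, "holdout")

    model_a = fit_risk_models(half_a, status_col, weight_col)
    model_b = fit_risk_models(half_b, status_col, weight_col)
    profiles = predict_risk(half_b, model_a)

    w = half_b[weight_col].to_numpy(dtype=float)
    s = half_b[status_col]
    obs_predm = s.isin([UNDETECTED_PREDIABETES, DIAGNOSED_PREDIABETES]).to_numpy()
    obs_udm = (s == UNDIAGNOSED_DIABETES).to_numpy()

    rows = []
    for band in AGE_BANDS:
        mask = (half_b["age_band"] == band).to_numpy()
        obs_p = float(w[mask & obs_predm].sum())
        obs_d = float(w[mask & obs_udm].sum())
        pred_p = float((w * profiles["p_total_predm"].to_numpy())[mask].sum())
        pred_d = float((w * profiles["p_undiag_dm"].to_numpy())[mask].sum())
        rows.append(
            {
                "age_band": band,
                "observed_predm": obs_p,
                "predicted_predm": pred_p,
                "ratio_predm": pred_p / obs_p if obs_p > 0 else float("nan"),
                "observed_udm": obs_d,
                "predicted_udm": pred_d,
                "ratio_udm": pred_d / obs_d if obs_d > 0 else float("nan"),
            }
        )
    by_age = pd.DataFrame(rows).set_index("age_band")

    diff = np.abs(model_a.polytomous_coef - model_b.polytomous_coef)
    return ValidationReport(
        by_age=by_age,
        n_fit=len(half_a),
        n_holdout=len(half_b),
        max_abs_coef_diff=float(diff.max()),
        mean_abs_coef_diff=float(diff.mean()),
        model_fit=model_a,
        model_holdout=model_b,
    )
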