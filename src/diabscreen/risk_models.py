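"""Survey-weighted polytomous and binary logistic risk models.

The central model is a three-category (polytomous) logistic regression of
glycemic status — normal (reference), total prediabetes, undiagnosed
diabetes — on the shared covariate layout, maximized by Newton-Raphson on the
weight-multiplied multinomial log-likelihood.  A companion binary logistic
model predicts diagnosed prediabetes; subtracting its prediction from the
total-prediabetes probability yields each person's probability of *undetected*
prediabetes.

Sampling weights enter as frequency-style multipliers of the log-likelihood
terms (pseudo-maximum likelihood).  Weights are normalized to mean 1
internally, which makes both the coefficients and the reported model-based
standard errors (inverse observed Hessian) invariant to rescaling all weights
by a positive constant; the effective sample size behind the standard errors
is the number of records, not the population total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .design import DESIGN_COLUMNS, design_matrix, weighted_mean_design
from .errors import ConvergenceError, DegenerateDataError, SchemaError

#: non-reference outcomes of the polytomous model, in coefficient-row order
POLY_OUTCOMES = ["total_predm", "undiag_dm"]

PROFILE_COLUMNS = ["p_normal", "p_total_predm", "p_undiag_dm", "p_diag_predm", "p_undet_predm"]

_MAX_ITER = 100
_GRAD_TOL = 1e-8  # on the mean (per unit normalized weight) score
_RIDGE = 1e-6


@dataclass
class FittedRiskModel:
    """Coefficients of the polytomous model and auxiliary binary models.

    ``polytomous_coef`` has one row per non-reference outcome
    (:data:`POLY_OUTCOMES`), each of length ``1 + len(DESIGN_COLUMNS)`` with
    the intercept first.  ``polytomous_se`` is laid out identically.
    """

    polytomous_coef: np.ndarray
    polytomous_se: np.ndarray
    diag_predm_coef: np.ndarray | None = None
    diag_predm_se: np.ndarray | None = None
    diag_dm_coef: np.ndarray | None = None
    converged: bool = True
    n_iterations: int = 0
    loglik: float = float("nan")
    column_names: list = field(default_factory=lambda: ["intercept"] + list(DESIGN_COLUMNS))

    # -- serialization (plain JSON, exact round-trip via float repr) ----------

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "column_names": list(self.column_names),
            "outcomes": list(POLY_OUTCOMES),
            "polytomous_coef": arr(self.polytomous_coef),
            "polytomous_se": arr(self.polytomous_se),
            "diag_predm_coef": arr(self.diag_predm_coef),
            "diag_predm_se": arr(self.diag_predm_se),
            "diag_dm_coef": arr(self.diag_dm_coef),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "loglik": float(self.loglik),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedRiskModel":
        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        return cls(
            polytomous_coef=arr(d["polytomous_coef"]),
            polytomous_se=arr(d["polytomous_se"]),
            diag_predm_coef=arr(d.get("diag_predm_coef")),
            diag_predm_se=arr(d.get("diag_predm_se")),
            diag_dm_coef=arr(d.get("diag_dm_coef")),
            converged=d.get("converged", True),
            n_iterations=d.get("n_iterations", 0),
            loglik=d.get("loglik", float("nan")),
            column_names=list(d["column_names"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedRiskModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ConcordanceReport:
    """Pairwise concordance of scores against a binary outcome."""

    pct_concordant: float
    pct_discordant: float
    pct_tied: float
    n_pairs: int
    somers_d: float
    c_statistic: float


# ---------------------------------------------------------------------------
# Newton-Raphson multinomial fitter
# ---------------------------------------------------------------------------


def _multinomial_loglik(B: np.ndarray, X: np.ndarray, Y: np.ndarray, w: np.ndarray) -> float:
    eta = X @ B.T  # (n, K-1)
    m = np.maximum(0.0, eta.max(axis=1))
    log_denom = m + np.log(np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1))
    chosen = (Y[:, :] * eta).sum(axis=1)  # eta of chosen non-reference outcome, 0 for reference
    return float((w * (chosen - log_denom)).sum())


def _fit_multinomial_core(X: np.ndarray, y: np.ndarray, w: np.ndarray, n_outcomes: int):
    """Newton-Raphson pseudo-MLE for a reference-coded multinomial logit.

    ``y`` takes values 0..n_outcomes with 0 the reference.  Returns
    ``(B, se, loglik, n_iter, converged)`` with ``B`` of shape
    ``(n_outcomes, p)``.
    """
    n, p = X.shape
    counts = np.bincount(y, minlength=n_outcomes + 1)
    if (counts == 0).any():
        empty = [int(k) for k in np.flatnonzero(counts == 0)]
        raise DegenerateDataError(f"outcome categories {empty} have no observations")

    w = w / w.mean()  # weight-scale invariance; effective n = len(y)
    Y = np.zeros((n, n_outcomes))
    for k in range(n_outcomes):
        Y[:, k] = y == (k + 1)

    B = np.zeros((n_outcomes, p))
    ll = _multinomial_loglik(B, X, Y, w)
    tol = _GRAD_TOL * n
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = X @ B.T
        m = np.maximum(0.0, eta.max(axis=1))
        denom = np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1)
        P = np.exp(eta - m[:, None]) / denom[:, None]  # (n, K-1)

        R = w[:, None] * (Y - P)
        grad = (X.T @ R).T.ravel()  # (K-1)*p, outcome-major
        if np.abs(grad).max() < tol:
            converged = True
            break

        H = np.empty((n_outcomes * p, n_outcomes * p))
        for k in range(n_outcomes):
            for l in range(k, n_outcomes):
                d = w * (P[:, k] * ((k == l) - P[:, l]))
                block = X.T @ (X * d[:, None])
                H[k * p : (k + 1) * p, l * p : (l + 1) * p] = block
                H[l * p : (l + 1) * p, k * p : (k + 1) * p] = block.T

        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + _RIDGE * np.eye(H.shape[0]), grad)
        if not np.isfinite(step).all():
            step = np.linalg.solve(H + _RIDGE * np.eye(H.shape[0]), grad)

        # step-halving to guarantee ascent
        new_B = B + step.reshape(n_outcomes, p)
        new_ll = _multinomial_loglik(new_B, X, Y, w)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-10) and halvings < 30:
            step *= 0.5
            halvings += 1
            new_B = B + step.reshape(n_outcomes, p)
            new_ll = _multinomial_loglik(new_B, X, Y, w)
        B, ll = new_B, new_ll

    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {_MAX_ITER} iterations "
            "(possible separation)",
            last_coef=B,
            n_iterations=it,
        )

    # model-based SEs from the observed information at the optimum
    eta = X @ B.T
    m = np.maximum(0.0, eta.max(axis=1))
    denom = np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1)
    P = np.exp(eta - m[:, None]) / denom[:, None]
    H = np.empty((n_outcomes * p, n_outcomes * p))
    for k in range(n_outcomes):
        for l in range(k, n_outcomes):
            d = w * (P[:, k] * ((k == l) - P[:, l]))
            block = X.T @ (X * d[:, None])
            H[k * p : (k + 1) * p, l * p : (l + 1) * p] = block
            H[l * p : (l + 1) * p, k * p : (k + 1) * p] = block.T
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.inv(H + _RIDGE * np.eye(H.shape[0]))
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None)).reshape(n_outcomes, p)
    return B, se, ll, it, converged


def _design_with_intercept(frame: pd.DataFrame) -> np.ndarray:
    X = design_matrix(frame)
    return np.column_stack([np.ones(len(X)), X])


def fit_polytomous(
    frame: pd.DataFrame,
    outcome,
    weight_col: str = "weight",
) -> FittedRiskModel:
    """Fit the 3-category glycemic risk model.

    ``outcome`` is an integer array/Series over the frame's rows with
    0 = normal (reference), 1 = total prediabetes, 2 = undiagnosed diabetes
    (see :func:`diabscreen.classification.collapse_status`).
    """
    X = _design_with_intercept(frame)
    y = np.asarray(outcome, dtype=int)
    if y.shape != (len(frame),):
        raise SchemaError("outcome must align with the survey frame rows")
    w = frame[weight_col].to_numpy(dtype=float)
    B, se, ll, it, conv = _fit_multinomial_core(X, y, w, n_outcomes=2)
    return FittedRiskModel(
        polytomous_coef=B, polytomous_se=se, converged=conv, n_iterations=it, loglik=ll
    )


def fit_binary(frame: pd.DataFrame, outcome, weight_col: str = "weight"):
    """Weighted binary logistic fit over the shared design layout.

    Returns ``(coef, se)`` of length ``1 + len(DESIGN_COLUMNS)`` (intercept
    first).  Same convergence contract as :func:`fit_polytomous`.
    """
    X = _design_with_intercept(frame)
    y = np.asarray(outcome, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise SchemaError("binary outcome must be coded 0/1")
    w = frame[weight_col].to_numpy(dtype=float)
    B, se, _, _, _ = _fit_multinomial_core(X, y, w, n_outcomes=1)
    return B[0], se[0]


def fit_risk_models(
    frame: pd.DataFrame,
    status_col: str = "status",
    weight_col: str = "weight",
) -> FittedRiskModel:
    """Fit the polytomous model plus the diagnosed-prediabetes binary model."""
    from .classification import DIAGNOSED_PREDIABETES, collapse_status

    y = collapse_status(frame[status_col])
    model = fit_polytomous(frame, y, weight_col)
    diag_pd = (frame[status_col] == DIAGNOSED_PREDIABETES).to_numpy().astype(int)
    model.diag_predm_coef, model.diag_predm_se = fit_binary(frame, diag_pd, weight_col)
    return model


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def _poly_probs(X1: np.ndarray, coef: np.ndarray):
    eta = X1 @ coef.T  # (n, 2)
    m = np.maximum(0.0, eta.max(axis=1))
    denom = np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1)
    p_ref = np.exp(-m) / denom
    P = np.exp(eta - m[:, None]) / denom[:, None]
    return p_ref, P


def predict_risk(frame: pd.DataFrame, model: FittedRiskModel) -> pd.DataFrame:
    """Per-person risk profile for every record of a survey frame.

    Returns a frame (aligned with the input index) with the probabilities of
    normal status, total prediabetes, undiagnosed diabetes, diagnosed
    prediabetes, and undetected prediabetes.  Undetected prediabetes is the
    total-prediabetes probability minus the diagnosed-prediabetes probability,
    clamped at zero (the subtraction can go slightly negative for covariate
    patterns with high diagnosis propensity).
    """
    X1 = _design_with_intercept(frame)
    if X1.shape[1] != model.polytomous_coef.shape[1]:
        raise SchemaError(
            f"design has {X1.shape[1]} columns but model expects {model.polytomous_coef.shape[1]}"
        )
    p_normal, P = _poly_probs(X1, model.polytomous_coef)
    if model.diag_predm_coef is not None:
        p_diag_predm = expit(X1 @ model.diag_predm_coef)
    else:
        p_diag_predm = np.zeros(len(X1))
    p_total_predm = P[:, 0]
    p_undiag_dm = P[:, 1]
    p_undet_predm = np.maximum(0.0, p_total_predm - p_diag_predm)
    return pd.DataFrame(
        {
            "p_normal": p_normal,
            "p_total_predm": p_total_predm,
            "p_undiag_dm": p_undiag_dm,
            "p_diag_predm": p_diag_predm,
            "p_undet_predm": p_undet_predm,
        },
        index=frame.index,
    )


def apply_scale(profiles: pd.DataFrame, scale: float) -> pd.DataFrame:
    """Rescale the undiagnosed-diabetes and undetected-prediabetes columns."""
    out = profiles.copy()
    out["p_undiag_dm"] = out["p_undiag_dm"] * scale
    out["p_undet_predm"] = out["p_undet_predm"] * scale
    return out


# ---------------------------------------------------------------------------
# Summaries and diagnostics
# ---------------------------------------------------------------------------


def odds_ratios(model: FittedRiskModel) -> pd.DataFrame:
    """Elementwise exp of the slope coefficients (intercepts excluded)."""
    if not model.converged:
        raise ConvergenceError("odds ratios requested from a non-converged model")
    data = {out: np.exp(model.polytomous_coef[i, 1:]) for i, out in enumerate(POLY_OUTCOMES)}
    if model.diag_predm_coef is not None:
        data["diag_predm"] = np.exp(model.diag_predm_coef[1:])
    if model.diag_dm_coef is not None:
        data["diag_dm"] = np.exp(model.diag_dm_coef[1:])
    return pd.DataFrame(data, index=model.column_names[1:])


def _outcome_probability(x1: np.ndarray, model: FittedRiskModel, outcome: str) -> float:
    p_ref, P = _poly_probs(x1[None, :], model.polytomous_coef)
    if outcome == "normal":
        return float(p_ref[0])
    if outcome in POLY_OUTCOMES:
        return float(P[0, POLY_OUTCOMES.index(outcome)])
    raise SchemaError(f"unknown outcome '{outcome}'")


def standardized_effect(
    model: FittedRiskModel,
    characteristic: str,
    frame: pd.DataFrame,
    outcome: str = "undiag_dm",
    weight_col: str = "weight",
) -> float:
    """Percentage-point effect of a characteristic at population-average covariates.

    The predicted ``outcome`` probability is evaluated at the weighted mean
    design vector with the characteristic present vs absent; for a level of a
    categorical block, "present" switches the whole block to that level and
    "absent" to the block's reference level.  Returns (present - absent) x 100.
    """
    from .design import BLOCK_OF

    if characteristic not in DESIGN_COLUMNS:
        raise SchemaError(f"unknown characteristic '{characteristic}'")
    xbar = weighted_mean_design(frame, frame[weight_col].to_numpy(dtype=float))
    idx = {c: j for j, c in enumerate(DESIGN_COLUMNS)}

    x_on = xbar.copy()
    x_off = xbar.copy()
    if characteristic in BLOCK_OF:
        block_cols = [c for c, b in BLOCK_OF.items() if b == BLOCK_OF[characteristic]]
        for c in block_cols:  # reference level = all block indicators off
            x_on[idx[c]] = 0.0
            x_off[idx[c]] = 0.0
    x_on[idx[characteristic]] = 1.0
    x_off[idx[characteristic]] = 0.0

    one = np.ones(1)
    p_on = _outcome_probability(np.concatenate([one, x_on]), model, outcome)
    p_off = _outcome_probability(np.concatenate([one, x_off]), model, outcome)
    return (p_on - p_off) * 100.0


def concordance(scores, outcomes) -> ConcordanceReport:
    """Pairwise concordance of predicted scores against a 0/1 outcome.

    Over all positive-negative pairs, a pair is concordant when the positive
    scores strictly higher, discordant when strictly lower, tied on exact
    float equality.  Computed in O(n log n) via midranks; Somers' D is
    (C - D)/pairs and the c-statistic (C + T/2)/pairs.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(int)
    if s.shape != y.shape:
        raise SchemaError("scores and outcomes must align")
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise DegenerateDataError("concordance needs at least one positive and one negative outcome")
    n_pairs = n1 * n0

    # tied pairs per distinct score value
    order = np.argsort(s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    boundaries = np.flatnonzero(np.diff(s_sorted) != 0)
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries + 1, [len(s)]])
    pos_cum = np.concatenate([[0], np.cumsum(y_sorted)])
    group_n = ends - starts
    group_pos = pos_cum[ends] - pos_cum[starts]
    tied = int((group_pos * (group_n - group_pos)).sum())

    ranks = rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / n_pairs
    concordant = auc * n_pairs - 0.5 * tied
    discordant = n_pairs - concordant - tied

    return ConcordanceReport(
        pct_concordant=100.0 * concordant / n_pairs,
        pct_discordant=100.0 * discordant / n_pairs,
        pct_tied=100.0 * tied / n_pairs,
        n_pairs=n_pairs,
        somers_d=(concordant - discordant) / n_pairs,
        c_statistic=(concordant + 0.5 * tied) / n_pairs,
    )


def calibrate_scale(predicted_totals, national_targets) -> float:
    """Single scale factor aligning predicted national totals with targets.

    ``s = sum(targets) / sum(predicted)``; multiplying every profile's
    undiagnosed-diabetes and undetected-prediabetes probabilities by ``s``
    makes the combined predicted total match the combined target exactly.
    """

    def total(x) -> float:
        if isinstance(x, dict):
            return float(sum(x.values()))
        return float(np.sum(np.asarray(x, dtype=float)))

    pred = total(predicted_totals)
    if pred <= 0:
        raise DegenerateDataError("predicted total must be positive to calibrate")
    return total(national_targets) / pred
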