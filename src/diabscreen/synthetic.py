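"""Synthetic survey populations with the structure the analysis assumes.

Two generators share one covariate model:

* :func:`generate_model_survey` — an examination-style survey (NHANES-like):
  partial lab panel, prediabetes/diabetes diagnosis flags, pregnancy flag.
  Latent glycemic state is drawn from the configured polytomous risk model so
  fitted coefficients can be checked against the generating truth.
* :func:`generate_projection_survey` — an expenditure-style survey
  (MEPS-like): the same covariates plus annual visit counts in five care
  settings whose means rise with the record's true undiagnosed-diabetes
  probability; no lab values.

Both are fully vectorized and bit-reproducible given ``config.seed``; the two
surveys use distinct child streams of that seed so they are independent draws
from the same scenario.

Latent truth (``latent_state``, ``p_predm_true``, ``p_udm_true``) is kept as
extra columns for recovery and calibration tests; real surveys do not carry
these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import classification as cls
from .config import VISIT_SETTINGS, ScenarioConfig
from .design import AGE_BANDS, BMI_CLASSES, RACE_ETH, SURVEY_WAVES, design_matrix

#: per-test sampling interval for each latent category; diabetes ranges are
#: capped at physiologically plausible maxima (classification only depends on
#: range membership, so the within-range law is uniform).
LAB_RANGES = {
    "hba1c": {"normal": (4.8, 5.7), "prediabetes": (5.7, 6.5), "diabetes": (6.5, 14.0)},
    "fpg": {"normal": (80.0, 100.0), "prediabetes": (100.0, 126.0), "diabetes": (126.0, 300.0)},
    "ogtt": {"normal": (90.0, 140.0), "prediabetes": (140.0, 200.0), "diabetes": (200.0, 400.0)},
}

LATENT_STATES = ["normal", "prediabetes", "diabetes"]

VISIT_COLUMNS = [f"visits_{s}" for s in VISIT_SETTINGS]


def _draw_covariates(n: int, cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    cs = cfg.covariate_spec
    age_idx = rng.choice(len(AGE_BANDS), size=n, p=np.asarray(cs.age_probs, dtype=float))
    race_idx = rng.choice(len(RACE_ETH), size=n, p=np.asarray(cs.race_probs, dtype=float))

    # BMI class conditional on age band
    bmi_probs = np.asarray(cs.bmi_probs_by_age, dtype=float)[age_idx]  # (n, 3)
    cum = np.cumsum(bmi_probs, axis=1)
    u = rng.random(n)
    bmi_idx = (u[:, None] > cum).sum(axis=1).clip(0, len(BMI_CLASSES) - 1)

    frame = pd.DataFrame(
        {
            "male": (rng.random(n) < cs.male_p).astype(int),
            "age_band": np.array(AGE_BANDS, dtype=object)[age_idx],
            "race_eth": np.array(RACE_ETH, dtype=object)[race_idx],
            "bmi_class": np.array(BMI_CLASSES, dtype=object)[bmi_idx],
        }
    )

    # Chronic conditions / smoking conditional on age band and BMI class
    for name, spec in cs.conditions.items():
        p = expit(spec.base + spec.age_slope * age_idx + spec.bmi_slope * bmi_idx)
        frame[name] = (rng.random(n) < p).astype(int)

    frame["income_k"] = rng.lognormal(mean=np.log(cs.income_median_k), sigma=cs.income_sigma, size=n)

    # Nested draw: Medicaid implies insured.
    u_ins = rng.random(n)
    frame["insured"] = (u_ins < cs.insured_p).astype(int)
    frame["medicaid"] = (u_ins < cs.medicaid_p).astype(int)

    wave_idx = rng.choice(len(SURVEY_WAVES), size=n, p=np.asarray(cs.wave_probs, dtype=float))
    frame["survey_wave"] = np.array(SURVEY_WAVES, dtype=object)[wave_idx]

    frame["pregnant"] = ((frame["male"] == 0) & (rng.random(n) < cs.pregnant_rate_female)).astype(int)
    return frame


def _solve_intercept(eta: np.ndarray, target_rate: float) -> float:
    """Intercept c with mean(expit(eta + c)) == target_rate over the population."""
    if target_rate <= 0.0:
        return -np.inf
    return brentq(lambda c: float(expit(eta + c).mean()) - target_rate, -40.0, 40.0, xtol=1e-12)


def _glycemic_probabilities(X: np.ndarray, cfg: ScenarioConfig):
    tm = cfg.true_model
    eta_p = tm.predm_intercept + X @ tm.predm_slopes
    eta_d = tm.udm_intercept + X @ tm.udm_slopes
    denom = 1.0 + np.exp(eta_p) + np.exp(eta_d)
    return np.exp(eta_p) / denom, np.exp(eta_d) / denom  # (p_predm, p_udm)


def _base_population(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = int(cfg.population_size)
    frame = _draw_covariates(n, cfg, rng)
    frame.insert(0, "id", np.arange(n))
    ws = cfg.weight_spec
    frame.insert(1, "weight", rng.lognormal(mean=np.log(ws.median), sigma=ws.sigma, size=n))

    X = design_matrix(frame)
    p_predm, p_udm = _glycemic_probabilities(X, cfg)
    frame["p_predm_true"] = p_predm
    frame["p_udm_true"] = p_udm

    # Diagnosed diabetes first (its own logistic model, intercept solved to hit
    # the configured overall rate); the remaining adults draw a latent 3-state
    # outcome from the polytomous model, so the post-exclusion sample follows
    # the generating coefficients exactly.
    eta_dd = X @ cfg.true_model.diag_dm_slopes
    c_dd = _solve_intercept(eta_dd, cfg.diagnosis_spec.diag_dm_rate)
    diag_dm = rng.random(n) < expit(eta_dd + c_dd)
    frame["diagnosed_diabetes"] = diag_dm.astype(int)

    u = rng.random(n)
    latent = np.where(u < p_predm, "prediabetes", np.where(u < p_predm + p_udm, "diabetes", "normal"))
    latent = latent.astype(object)
    latent[diag_dm] = "diabetes"
    frame["latent_state"] = latent

    # X is needed again for the prediabetes-diagnosis model
    frame.attrs["_design"] = X
    return frame


def generate_model_survey(config: ScenarioConfig) -> pd.DataFrame:
    """Generate the examination-style survey (labs + diagnosis flags)."""
    config.validate()
    rng = np.random.default_rng([int(config.seed), 1])
    frame = _base_population(config, rng)
    X = frame.attrs.pop("_design")
    n = len(frame)

    # Prediabetes diagnosis only among latent prediabetes, from its own
    # logistic model with the intercept solved to the configured rate.
    is_predm = (frame["latent_state"] == "prediabetes").to_numpy()
    diag_pd = np.zeros(n, dtype=bool)
    if is_predm.any() and config.diagnosis_spec.diag_predm_rate > 0:
        eta = X[is_predm] @ config.true_model.diag_predm_slopes
        c = _solve_intercept(eta, config.diagnosis_spec.diag_predm_rate)
        diag_pd[is_predm] = rng.random(int(is_predm.sum())) < expit(eta + c)
    frame["diagnosed_prediabetes"] = diag_pd.astype(int)

    # Lab panel assignment; every record keeps at least one test (the most
    # frequently administered one) so panels are never empty.
    la = config.lab_assignment
    assign_p = {"hba1c": la.hba1c, "fpg": la.fpg, "ogtt": la.ogtt}
    assigned = {t: rng.random(n) < p for t, p in assign_p.items()}
    none_assigned = ~np.logical_or.reduce(list(assigned.values()))
    if none_assigned.any():
        fallback = max(assign_p, key=assign_p.get)
        assigned[fallback] |= none_assigned

    latent = frame["latent_state"].to_numpy()
    state_idx = {s: i for i, s in enumerate(LATENT_STATES)}
    latent_idx = np.vectorize(state_idx.get)(latent)
    for test, mask in assigned.items():
        cat_idx = latent_idx.copy()
        if config.discordance_rate > 0:
            flip = rng.random(n) < config.discordance_rate
            shift = rng.integers(1, 3, size=n)
            cat_idx = np.where(flip, (cat_idx + shift) % 3, cat_idx)
        lo = np.array([LAB_RANGES[test][s][0] for s in LATENT_STATES])[cat_idx]
        hi = np.array([LAB_RANGES[test][s][1] for s in LATENT_STATES])[cat_idx]
        values = lo + rng.random(n) * (hi - lo)
        col = cls.TEST_COLUMNS[test]
        frame[col] = np.where(mask, values, np.nan)

    return frame


def generate_projection_survey(config: ScenarioConfig) -> pd.DataFrame:
    """Generate the expenditure-style survey (visit counts, no labs)."""
    config.validate()
    rng = np.random.default_rng([int(config.seed), 2])
    frame = _base_population(config, rng)
    frame.attrs.pop("_design", None)
    n = len(frame)

    vs = config.visit_spec
    p_udm = frame["p_udm_true"].to_numpy()
    no_visits = rng.random(n) < vs.zero_inflation
    for setting in VISIT_SETTINGS:
        mean = vs.settings[setting].mean(p_udm)
        counts = rng.poisson(np.clip(mean, 0.0, None))
        counts[no_visits] = 0
        frame[f"visits_{setting}"] = counts

    return frame
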