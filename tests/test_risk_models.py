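"""Weighted polytomous/binary fitting, prediction, and diagnostics."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from diabscreen import (
    ScenarioConfig,
    apply_exclusions,
    apply_scale,
    calibrate_scale,
    classify_frame,
    collapse_status,
    concordance,
    fit_binary,
    fit_polytomous,
    generate_model_survey,
    odds_ratios,
    predict_risk,
    standardized_effect,
)
from diabscreen.design import N_DESIGN
from diabscreen.errors import DegenerateDataError
from diabscreen.risk_models import FittedRiskModel, _fit_multinomial_core


def _truth_matrix(cfg):
    tm = cfg.true_model
    return np.vstack(
        [
            np.concatenate([[tm.predm_intercept], tm.predm_slopes]),
            np.concatenate([[tm.udm_intercept], tm.udm_slopes]),
        ]
    )


def _classified(n, seed):
    frame = generate_model_survey(ScenarioConfig(population_size=n, seed=seed))
    kept, _, _ = apply_exclusions(frame)
    return classify_frame(kept)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def test_null_model_recovers_category_log_odds(rng):
    """Outcome independent of covariates: slopes ~0, intercepts = log share ratios."""
    frame = generate_model_survey(ScenarioConfig(population_size=8000, seed=2))
    frame = frame.assign(weight=1.0)
    y = rng.choice([0, 1, 2], size=len(frame), p=[0.5, 0.4, 0.1])
    model = fit_polytomous(frame, y)
    counts = np.bincount(y)
    for k in (0, 1):
        z = model.polytomous_coef[k, 1:] / model.polytomous_se[k, 1:]
        assert (np.abs(z) < 3).mean() >= 0.95
        expected = np.log(counts[k + 1] / counts[0])
        assert abs(model.polytomous_coef[k, 0] - expected) < 3 * model.polytomous_se[k, 0]


def test_balanced_intercept_only_binary_fit_is_zero():
    X = np.ones((200, 1))
    y = np.array([0, 1] * 100)
    B, _, _, _, _ = _fit_multinomial_core(X, y, np.ones(200), n_outcomes=1)
    assert abs(B[0, 0]) < 1e-6


def test_multinomial_matches_generic_optimizer():
    """Two covariates, equal weights: Newton fit equals a BFGS maximization
    of the same likelihood (independent optimization route)."""
    rng = np.random.default_rng(7)
    n = 200
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    eta1 = 0.3 + 0.8 * X[:, 1] - 0.5 * X[:, 2]
    eta2 = -0.7 + 0.2 * X[:, 1] + 0.9 * X[:, 2]
    denom = 1 + np.exp(eta1) + np.exp(eta2)
    u = rng.random(n)
    y = np.where(u < np.exp(eta1) / denom, 1, np.where(u < (np.exp(eta1) + np.exp(eta2)) / denom, 2, 0))

    B, _, _, _, _ = _fit_multinomial_core(X, y, np.ones(n), n_outcomes=2)

    def negll(theta):
        b = theta.reshape(2, 3)
        eta = X @ b.T
        log_denom = np.log(1 + np.exp(eta).sum(axis=1))
        chosen = np.where(y == 0, 0.0, eta[np.arange(n), np.maximum(y - 1, 0)])
        return -(chosen - log_denom).sum()

    res = minimize(negll, np.zeros(6), method="BFGS", options={"gtol": 1e-10, "maxiter": 2000})
    assert np.abs(B.ravel() - res.x).max() < 1e-5


def test_multinomial_matches_statsmodels():
    """Independent library cross-check on an unweighted fit."""
    sm = pytest.importorskip("statsmodels.api")
    frame = _classified(1500, seed=31)
    frame = frame.assign(weight=1.0)
    y = collapse_status(frame["status"])
    model = fit_polytomous(frame, y)

    from diabscreen.risk_models import _design_with_intercept

    X = _design_with_intercept(frame)
    ref = sm.MNLogit(y, X).fit(method="newton", maxiter=200, disp=False)
    assert np.abs(model.polytomous_coef - ref.params.T).max() < 1e-5


def test_weight_scale_invariance():
    frame = _classified(3000, seed=17)
    y = collapse_status(frame["status"])
    m1 = fit_polytomous(frame, y)
    m2 = fit_polytomous(frame.assign(weight=frame["weight"] * 1e4), y)
    np.testing.assert_allclose(m1.polytomous_coef, m2.polytomous_coef, atol=1e-10)
    np.testing.assert_allclose(m1.polytomous_se, m2.polytomous_se, atol=1e-10)


def test_binary_fit_recovers_generating_slopes():
    """The diagnosis flag is generated conditional on latent prediabetes, so
    fitting on that subpopulation recovers the generating diagnosis slopes."""
    cfg = ScenarioConfig(population_size=60_000, seed=19)
    frame = generate_model_survey(cfg)
    predm = frame[frame["latent_state"] == "prediabetes"]
    outcome = predm["diagnosed_prediabetes"].to_numpy()
    coef, se = fit_binary(predm, outcome)
    z = (coef[1:] - cfg.true_model.diag_predm_slopes) / se[1:]
    assert (np.abs(z) < 3).mean() >= 0.90


def test_slope_bias_shrinks_with_sample_size():
    """Mean absolute slope error decreases as the fitted sample grows."""
    seeds = [101, 102, 103]
    errors = []
    for n in (5_000, 20_000, 80_000):
        errs = []
        for seed in seeds:
            cfg = ScenarioConfig(population_size=n, seed=seed)
            frame = _classified(n, seed)
            y = collapse_status(frame["status"])
            model = fit_polytomous(frame, y)
            errs.append(np.abs(model.polytomous_coef[:, 1:] - _truth_matrix(cfg)[:, 1:]).mean())
        errors.append(np.mean(errs))
    assert errors[0] > errors[1] > errors[2]


def test_empty_outcome_category_raises():
    frame = _classified(500, seed=5)
    y = np.zeros(len(frame), dtype=int)
    with pytest.raises(DegenerateDataError):
        fit_polytomous(frame, y)
    with pytest.raises(DegenerateDataError):
        fit_binary(frame, np.zeros(len(frame), dtype=int))


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def _model_from_truth(cfg):
    tm = cfg.true_model
    B = _truth_matrix(cfg)
    return FittedRiskModel(
        polytomous_coef=B,
        polytomous_se=np.zeros_like(B),
        diag_predm_coef=np.concatenate([[-3.0], tm.diag_predm_slopes]),
    )


def test_zero_coefficient_prediction_is_symmetric(model_survey):
    zeros = FittedRiskModel(
        polytomous_coef=np.zeros((2, 1 + N_DESIGN)),
        polytomous_se=np.zeros((2, 1 + N_DESIGN)),
        diag_predm_coef=np.zeros(1 + N_DESIGN),
    )
    prof = predict_risk(model_survey.head(10), zeros)
    assert np.allclose(prof["p_normal"], 1 / 3)
    assert np.allclose(prof["p_total_predm"], 1 / 3)
    assert np.allclose(prof["p_undiag_dm"], 1 / 3)
    assert np.allclose(prof["p_diag_predm"], 1 / 2)
    assert np.allclose(prof["p_undet_predm"], 0.0)  # clamped at zero


def test_prediction_matches_closed_form(model_survey, small_config):
    model = _model_from_truth(small_config)
    frame = model_survey.head(50)
    prof = predict_risk(frame, model)

    from diabscreen.design import design_matrix

    X = design_matrix(frame)
    tm = small_config.true_model
    e1 = np.exp(tm.predm_intercept + X @ tm.predm_slopes)
    e2 = np.exp(tm.udm_intercept + X @ tm.udm_slopes)
    denom = 1 + e1 + e2
    np.testing.assert_allclose(prof["p_total_predm"], e1 / denom, atol=1e-12)
    np.testing.assert_allclose(prof["p_undiag_dm"], e2 / denom, atol=1e-12)
    np.testing.assert_allclose(prof["p_normal"], 1 / denom, atol=1e-12)
    p_diag = expit(-3.0 + X @ tm.diag_predm_slopes)
    np.testing.assert_allclose(prof["p_undet_predm"], np.maximum(0, e1 / denom - p_diag), atol=1e-12)


def test_risk_profiles_normalize_and_respect_clamp(profiles):
    total = profiles["p_normal"] + profiles["p_total_predm"] + profiles["p_undiag_dm"]
    np.testing.assert_allclose(total, 1.0, atol=1e-9)
    assert (profiles["p_undet_predm"] >= 0).all()
    assert (profiles["p_undet_predm"] <= profiles["p_total_predm"] + 1e-12).all()


def test_predicted_risk_spans_orders_of_magnitude(profiles):
    """Across a realistic projection population the undiagnosed-diabetes
    probability spreads over roughly two orders of magnitude."""
    p = profiles["p_undiag_dm"]
    assert p.max() / p.min() > 50


def test_model_json_round_trip(tmp_path, fitted_model):
    path = tmp_path / "model.json"
    fitted_model.to_json(path)
    back = FittedRiskModel.from_json(path)
    np.testing.assert_array_equal(back.polytomous_coef, fitted_model.polytomous_coef)
    np.testing.assert_array_equal(back.diag_predm_coef, fitted_model.diag_predm_coef)
    assert back.column_names == fitted_model.column_names


# ---------------------------------------------------------------------------
# Odds ratios and standardized effects
# ---------------------------------------------------------------------------


def test_odds_ratios_exponentiate_slopes():
    B = np.zeros((2, 1 + N_DESIGN))
    B[0, 1] = np.log(2.0)  # male slope, prediabetes outcome
    B[1, 0] = 5.0  # intercept must be excluded
    model = FittedRiskModel(polytomous_coef=B, polytomous_se=np.zeros_like(B))
    table = odds_ratios(model)
    assert table.loc["male", "total_predm"] == pytest.approx(2.0)
    assert (table.drop(index="male")["total_predm"] == 1.0).all()
    assert (table["undiag_dm"] == 1.0).all()


def test_standardized_effect_zero_slope_is_zero(classified_survey):
    B = np.zeros((2, 1 + N_DESIGN))
    model = FittedRiskModel(polytomous_coef=B, polytomous_se=np.zeros_like(B))
    assert standardized_effect(model, "obese", classified_survey) == pytest.approx(0.0)


def test_standardized_effect_matches_manual_softmax(classified_survey, small_config):
    model = _model_from_truth(small_config)
    effect = standardized_effect(model, "hypertension", classified_survey, outcome="undiag_dm")

    from diabscreen.design import DESIGN_COLUMNS, weighted_mean_design

    xbar = weighted_mean_design(classified_survey)
    j = DESIGN_COLUMNS.index("hypertension")
    tm = small_config.true_model

    def p_udm(x):
        e1 = np.exp(tm.predm_intercept + x @ tm.predm_slopes)
        e2 = np.exp(tm.udm_intercept + x @ tm.udm_slopes)
        return e2 / (1 + e1 + e2)

    x_on, x_off = xbar.copy(), xbar.copy()
    x_on[j], x_off[j] = 1.0, 0.0
    assert effect == pytest.approx((p_udm(x_on) - p_udm(x_off)) * 100, abs=1e-10)


def test_obesity_effect_is_positive_single_digit(classified_survey, small_config):
    """With the generating obesity odds ratio (~3), obesity raises the
    undiagnosed-diabetes probability by a positive, single-digit number of
    percentage points in a middle-aged population."""
    model = _model_from_truth(small_config)
    pop = classified_survey[classified_survey["age_band"] == "45-54"]
    effect = standardized_effect(model, "obese", pop, outcome="undiag_dm")
    assert 0.0 < effect < 10.0


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


def brute_force_concordance(scores, outcomes):
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    diff = pos[:, None] - neg[None, :]
    return (diff > 0).sum(), (diff < 0).sum(), (diff == 0).sum()


def test_concordance_perfect_separation():
    rep = concordance([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert rep.pct_concordant == pytest.approx(100.0)
    assert rep.c_statistic == pytest.approx(1.0)
    assert rep.somers_d == pytest.approx(1.0)


def test_concordance_all_tied():
    rep = concordance([0.5] * 6, [1, 0, 1, 0, 1, 0])
    assert rep.pct_tied == pytest.approx(100.0)
    assert rep.c_statistic == pytest.approx(0.5)
    assert rep.somers_d == pytest.approx(0.0)


def test_concordance_identities_and_oracle(rng):
    for _ in range(60):
        n = int(rng.integers(10, 200))
        scores = rng.choice(np.round(rng.random(12), 3), size=n)
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            continue
        rep = concordance(scores, y)
        C, D, T = brute_force_concordance(scores, y)
        assert rep.n_pairs == C + D + T
        assert rep.pct_concordant == pytest.approx(100 * C / rep.n_pairs)
        assert rep.pct_discordant == pytest.approx(100 * D / rep.n_pairs)
        assert rep.pct_tied == pytest.approx(100 * T / rep.n_pairs)
        assert rep.c_statistic == pytest.approx((C + 0.5 * T) / rep.n_pairs, abs=1e-6)
        assert rep.somers_d == pytest.approx((C - D) / rep.n_pairs, abs=1e-6)


def test_concordance_single_class_raises():
    with pytest.raises(DegenerateDataError):
        concordance([0.1, 0.2], [1, 1])


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def test_calibration_factor_examples():
    assert calibrate_scale(88.2, 86.0) == pytest.approx(0.975, abs=0.001)
    assert calibrate_scale({"dm": 7.0, "predm": 79.0}, {"dm": 7.0, "predm": 79.0}) == 1.0
    with pytest.raises(DegenerateDataError):
        calibrate_scale(0.0, 86.0)


def test_rescaled_totals_hit_target_exactly(profiles, projection_survey):
    w = projection_survey["weight"].to_numpy()
    predicted = float((w * profiles["p_undiag_dm"]).sum() + (w * profiles["p_undet_predm"]).sum())
    target = predicted * 0.87
    s = calibrate_scale(predicted, target)
    scaled = apply_scale(profiles, s)
    rescaled = float((w * scaled["p_undiag_dm"]).sum() + (w * scaled["p_undet_predm"]).sum())
    assert rescaled == pytest.approx(target, rel=1e-9)
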