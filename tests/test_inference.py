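"""Predictor encoding, the mixed-logit fitter and model utilities."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from prosadapt._glmm import MixedLogitData, fit_mixed_logit_ml, \
    marginal_loglik
from prosadapt.inference import (MODEL_A_TERMS, ModelSpec, compare_fits,
                                 compare_with_without_IC,
                                 decompose_interaction, encode_predictors,
                                 fit_mixed_logit, fit_model_A, fit_model_B,
                                 parameter_recovery)


def toy_responses(n_participants=4, n_trials=8, seed=0, p_fun=None):
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(1, n_participants + 1):
        for t in range(1, n_trials + 1):
            cue = t % 2 == 0
            rep = (t // 2) % 2 == 0
            ic = 0.5 if cue else 0.0
            p = 0.5 if p_fun is None else p_fun(pid, cue, rep)
            rows.append({"participant_id": pid, "phase": "experiment1",
                         "trial_index": t, "predictive_cue": cue,
                         "repeated_noun": rep, "ic": ic,
                         "y": rng.binomial(18, p), "n": 18})
    return pd.DataFrame(rows)


def test_sum_coding_centering_and_interaction_codes():
    df = toy_responses()
    spec = ModelSpec(fixed_terms=tuple(MODEL_A_TERMS))
    enc = encode_predictors(df, spec)
    assert set(np.unique(enc["cue_c"])) == {-0.5, 0.5}
    assert enc["cue_c"].mean() == pytest.approx(0.0)       # balanced data
    assert enc["trial_z"].mean() == pytest.approx(0.0, abs=1e-12)
    assert enc["trial_z"].std(ddof=0) == pytest.approx(1.0)
    cell = enc[(enc["predictive_cue"]) & (~enc["repeated_noun"])]
    assert (cell["cue_c:rep_c"] == -0.25).all()


def test_missing_condition_columns_raise():
    df = toy_responses().drop(columns=["repeated_noun"])
    with pytest.raises(ValueError, match="missing"):
        encode_predictors(df, ModelSpec(fixed_terms=("rep_c",)))


def test_constant_ic_predictor_is_degenerate():
    df = toy_responses()
    df["ic"] = 0.0
    with pytest.raises(ValueError, match="degenerate"):
        fit_model_B(df)


def test_deviance_matches_brute_force_quadrature():
    """2 participants x 4 trials, random intercept: the adaptive-quadrature
    marginal deviance agrees with direct numerical integration to 1e-4."""
    y = np.array([3.0, 5, 7, 2, 6, 4, 1, 8])
    n = np.full(8, 10.0)
    X = np.column_stack([np.ones(8), np.tile([-0.5, 0.5], 4)])
    Z = np.ones((8, 1))
    groups = np.repeat([0, 1], 4)
    data = MixedLogitData(y, n, X, Z, groups)
    for beta, sd in [(np.array([0.1, 0.4]), 0.7),
                     (np.array([-0.3, 0.0]), 1.2)]:
        ll, _ = marginal_loglik(data, beta, np.array([[sd ** 2]]), n_quad=30)

        def group_loglik(g):
            idx = groups == g

            def integrand(b):
                p = 1 / (1 + np.exp(-(X[idx] @ beta + b)))
                return np.exp(np.sum(stats.binom.logpmf(y[idx], n[idx], p))
                              ) * stats.norm.pdf(b, 0, sd)
            v, _ = integrate.quad(integrand, -10, 10, limit=200)
            return np.log(v)

        brute = sum(group_loglik(g) for g in range(2))
        assert -2 * ll == pytest.approx(-2 * brute, abs=1e-4)


def test_response_modes_give_identical_fixed_effects(exp1_design, exp1_trace):
    from prosadapt.synthetic_gaze import calibration_params, \
        simulate_window_counts
    counts = simulate_window_counts(
        [exp1_design], exp1_trace, calibration_params(ic_weight=-1.0), 6,
        rng=np.random.default_rng(7))
    f_trial = fit_model_B(counts, response_mode="per_trial_binomial")
    f_sample = fit_model_B(counts, response_mode="per_sample_binary")
    assert np.allclose(f_trial.estimates, f_sample.estimates, atol=1e-3)
    assert f_trial.term("ic_c")["estimate"] == pytest.approx(
        f_sample.term("ic_c")["estimate"], abs=1e-3)


def test_estimates_invariant_to_relabeling_and_row_order(inhibition_counts):
    fit1 = fit_model_B(inhibition_counts)
    shuffled = inhibition_counts.sample(frac=1.0, random_state=3)
    relabeled = shuffled.assign(
        participant_id=shuffled["participant_id"].map(
            lambda i: f"subj_{i:02d}"))
    fit2 = fit_model_B(relabeled)
    assert np.allclose(fit1.estimates, fit2.estimates, atol=1e-4)
    assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-4)


def test_separable_data_is_flagged_not_silently_estimated():
    spec = ModelSpec(fixed_terms=("cue_c",), random_terms=("1",),
                     simplify=False)
    fit = fit_mixed_logit(separable_responses(), spec)
    assert (not fit.converged) or fit.singular or \
        not np.isfinite(fit.term("cue_c")["se"])


def test_single_participant_random_model_rejected():
    df = toy_responses(n_participants=1)
    with pytest.raises(ValueError, match="participants"):
        fit_model_B(df)


def separable_responses():
    rows = []
    for pid in (1, 2):
        for t in range(1, 9):
            cue = t % 2 == 0
            rows.append({"participant_id": pid, "trial_index": t,
                         "predictive_cue": cue, "repeated_noun": False,
                         "ic": 0.5 if cue else 0.0,
                         "y": 18 if cue else 0, "n": 18})
    return pd.DataFrame(rows)


def test_simplification_ladder_walks_down_and_logs_every_step():
    # perfectly separable data never converges cleanly, so the ladder must
    # walk from intercept+slope all the way to the plain GLM, logging each
    # structure it tried
    spec = ModelSpec(fixed_terms=("cue_c",), random_terms=("1", "cue_c"))
    fit = fit_mixed_logit(separable_responses(), spec)
    attempts = [line for line in fit.simplification_log
                if line.startswith("fit random=")]
    assert len(attempts) >= 3
    assert any("plain GLM" in line for line in fit.simplification_log)
    assert not fit.converged


def test_empty_and_single_level_subsets_rejected(inhibition_counts):
    only_repeated = inhibition_counts[inhibition_counts["repeated_noun"]]
    with pytest.raises(ValueError):
        decompose_interaction(only_repeated)


def test_identical_models_rejected_as_degenerate(inhibition_counts):
    fit = fit_model_B(inhibition_counts)
    with pytest.raises(ValueError, match="degenerate|nested"):
        compare_fits(fit, fit)


def test_comparison_requires_same_data(inhibition_counts):
    fit_full = fit_model_B(inhibition_counts)
    fit_half = fit_model_B(
        inhibition_counts[inhibition_counts["participant_id"] <= 9])
    with pytest.raises(ValueError, match="same data"):
        compare_fits(fit_full, fit_half)


def test_ic_model_comparison_favors_ic_under_strong_inhibition(
        inhibition_counts):
    comp = compare_with_without_IC(inhibition_counts)
    assert comp.df >= 1
    assert comp.p < 0.05
    assert comp.delta_aic < 0


def test_published_random_structures_fit_directly(inhibition_counts):
    from prosadapt.inference import PUBLISHED_RANDOM_STRUCTURES
    fit = fit_model_B(inhibition_counts,
                      random_terms=PUBLISHED_RANDOM_STRUCTURES["1B"],
                      simplify=False)
    assert fit.random_terms == ("1", "ic_c")
    assert len(fit.simplification_log) == 1
    # a no-random-effects published structure reduces to a plain GLM
    from prosadapt.inference import fit_model_C
    glm = fit_model_C(inhibition_counts,
                      random_terms=PUBLISHED_RANDOM_STRUCTURES["2C"],
                      simplify=False)
    assert glm.random_terms == ()
    assert glm.converged


def test_recovery_report_degenerate_single_draw():
    from prosadapt.synthetic_gaze import calibration_params
    rep = parameter_recovery(calibration_params(ic_weight=-2.0), n_sims=1,
                             seed=0)
    assert rep["degenerate"]
    assert np.isnan(rep["coverage_95"])
    assert rep["n_used"] + rep["n_fit_failures"] == 1


def test_recovery_rejects_unknown_parameter():
    with pytest.raises(ValueError):
        parameter_recovery(n_sims=1, parameter="dwell_mean_ms")
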