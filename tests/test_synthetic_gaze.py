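"""Gaze simulator: probability model, sampling modes, track loss."""

import numpy as np
import pytest
from scipy.special import expit

from prosadapt.synthetic_gaze import (GenerativeParams, calibration_params,
                                      inject_track_loss,
                                      participant_track_loss, sample_times,
                                      simulate_dataset, simulate_trial,
                                      simulate_window_counts,
                                      target_probability)
from helpers import make_trial


def test_sample_grid_covers_epoch_at_60hz():
    times = sample_times(GenerativeParams())
    assert times[0] == -200 and times[-1] == 800
    assert len(times) == 61
    # 18 samples inside the half-open analysis window
    assert ((times >= 150) & (times < 450)).sum() == 18


def test_target_probability_closed_form_and_zero_ic_identity():
    params = calibration_params(base_intercept=-0.2)
    cue_trial = make_trial(5, True, False)
    nocue_trial = make_trial(5, False, False)
    p_cue0 = target_probability(cue_trial, 0.0, (0.0, 0.0), params)
    p_nocue = target_probability(nocue_trial, 0.0, (0.0, 0.0), params)
    # with every effect zero, p is the plain logistic of the intercept
    assert np.allclose(p_cue0, expit(-0.2))
    # zero inhibition cost contributes nothing beyond the baseline
    assert np.allclose(p_cue0, p_nocue)


def test_mean_target_proportion_matches_generative_probability():
    params = calibration_params(base_intercept=0.3)
    trial = make_trial(1, False, False)
    rng = np.random.default_rng(0)
    draws = [simulate_trial(trial, 0.0, (0.0, 0.0), params, rng)["aoi"]
             .eq("target").mean() for _ in range(300)]
    se = np.std(draws) / np.sqrt(len(draws))
    assert abs(np.mean(draws) - expit(0.3)) < 4 * se + 1e-9


def test_simulation_is_deterministic_under_fixed_rng():
    params = GenerativeParams(mode="markov")
    trial = make_trial(3, True, True)
    a = simulate_trial(trial, 0.1, (0.2, -0.1), params,
                       np.random.default_rng(42))
    b = simulate_trial(trial, 0.1, (0.2, -0.1), params,
                       np.random.default_rng(42))
    assert a.equals(b)


def test_aoi_distribution_sums_to_one_and_spreads_nontarget():
    from prosadapt.synthetic_gaze import _aoi_matrix
    params = GenerativeParams(offscreen_share=0.2)
    p = np.array([0.3, 0.7])
    m = _aoi_matrix(p, params)
    assert np.allclose(m.sum(axis=1), 1.0)
    assert np.allclose(m[:, 1], m[:, 5])          # uniform over distractors
    assert np.allclose(m[:, 6], (1 - p) * 0.2)    # offscreen share


def test_negative_ic_weight_lowers_looks_on_disconfirmed_trials(
        exp1_design, exp1_trace):
    base = calibration_params()
    inhib = calibration_params(ic_weight=-2.0)
    rng1 = np.random.default_rng(7)
    rng2 = np.random.default_rng(7)
    c0 = simulate_window_counts([exp1_design], exp1_trace, base, 8, rng=rng1)
    c2 = simulate_window_counts([exp1_design], exp1_trace, inhib, 8, rng=rng2)
    mask = c0["predictive_cue"] & ~c0["repeated_noun"]
    p0 = c0[mask]["y"].sum() / c0[mask]["n"].sum()
    p2 = c2[mask]["y"].sum() / c2[mask]["n"].sum()
    assert p2 < p0


def test_dataset_shape_and_trackloss_free_run(exp1_design, exp1_trace):
    params = calibration_params(ic_weight=-1.0)
    table = simulate_dataset([exp1_design], exp1_trace, params,
                             n_participants=3,
                             rng=np.random.default_rng(1))
    assert table["participant_id"].nunique() == 3
    per_block = table.groupby("participant_id")["trial_index"].nunique()
    assert (per_block == 48).all()
    assert not table["aoi"].eq("lost").any()  # trackloss_rate == 0


def test_trackloss_rate_and_participant_flagging(exp1_design, exp1_trace):
    params = calibration_params()
    table = simulate_dataset([exp1_design], exp1_trace, params, 2,
                             rng=np.random.default_rng(3))
    rng = np.random.default_rng(9)
    assert inject_track_loss(table, 0.0, rng) is table
    lossy = inject_track_loss(table, 0.5, rng)
    frac = lossy["aoi"].eq("lost").mean()
    se = np.sqrt(0.25 / len(lossy))
    assert abs(frac - 0.5) < 3 * se
    # the study's exclusion rule: 37% loss is flagged, <20% is not
    p1 = lossy[lossy["participant_id"] == 1].copy()
    flags = participant_track_loss(lossy, threshold=0.2)
    assert flags["excluded"].all()  # both at ~50%
    clean = participant_track_loss(table, threshold=0.2)
    assert not clean["excluded"].any()


def test_markov_mode_produces_autocorrelated_dwells():
    params = GenerativeParams(mode="markov", dwell_mean_ms=400.0,
                              trackloss_rate=0.0)
    trial = make_trial(1, False, False)
    rng = np.random.default_rng(5)
    runs = []
    for _ in range(50):
        aoi = simulate_trial(trial, 0.0, (0.0, 0.0), params, rng)["aoi"]
        runs.append((aoi != aoi.shift()).sum())
    params_ind = GenerativeParams(mode="independent", trackloss_rate=0.0)
    runs_ind = []
    for _ in range(50):
        aoi = simulate_trial(trial, 0.0, (0.0, 0.0), params_ind, rng)["aoi"]
        runs_ind.append((aoi != aoi.shift()).sum())
    assert np.mean(runs) < np.mean(runs_ind)


def test_pathological_params_rejected():
    with pytest.raises(ValueError):
        GenerativeParams(trackloss_rate=1.0)
    with pytest.raises(ValueError):
        GenerativeParams(sampling_rate=0)
    with pytest.raises(ValueError):
        GenerativeParams(sd_participant_intercept=-1)
    with pytest.raises(ValueError):
        target_probability(make_trial(1, False, False), 0.0, (50.0, 0.0),
                           GenerativeParams())
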