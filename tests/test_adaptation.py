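"""Belief updating, prediction error and the inhibition-cost trace."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from prosadapt.adaptation import (BeliefState, InhibitionTrace, PEConfig,
                                  compute_trace, mu, prediction_error,
                                  trace_to_frame, update_belief)
from prosadapt.design import Language, Phase

from helpers import make_design, make_trial


def numeric_posterior_mean(a, b, n_grid=200_001):
    x = np.linspace(0.0, 1.0, n_grid)
    dens = x ** (a - 1) * (1 - x) ** (b - 1)
    return integrate.simpson(x * dens, x=x) / integrate.simpson(dens, x=x)


@pytest.mark.parametrize("counts,expected", [
    ((0, 0), 0.5), ((6, 6), 0.5), ((12, 6), 0.65)])
def test_posterior_mean_closed_form(counts, expected):
    assert mu(BeliefState(*counts)) == pytest.approx(expected, abs=1e-12)


def test_posterior_mean_matches_numeric_oracle_on_grid():
    for c in range(0, 31, 3):
        for d in range(0, 31, 3):
            assert mu(BeliefState(c, d)) == pytest.approx(
                numeric_posterior_mean(1 + c, 1 + d), abs=1e-6)


@pytest.mark.parametrize("cue,repeated,language,expected", [
    (True, True, "en", 0.04), (True, False, "en", 0.96),
    (True, True, "de", 0.08), (True, False, "de", 0.92),
    (False, True, "en", 0.0), (False, False, "de", 0.0)])
def test_prediction_error_defaults(cue, repeated, language, expected):
    t = make_trial(1, cue, repeated)
    assert prediction_error(t, language) == expected


def test_belief_updates_only_on_cue_trials():
    s = BeliefState()
    s = update_belief(s, make_trial(1, True, True))
    assert (s.n_confirmed, s.n_disconfirmed) == (1, 0)
    s2 = update_belief(BeliefState(3, 5), make_trial(2, False, True))
    assert (s2.n_confirmed, s2.n_disconfirmed) == (3, 5)
    s3 = update_belief(s, make_trial(3, True, False))
    assert (s3.n_confirmed, s3.n_disconfirmed) == (1, 1)


def test_belief_after_one_experiment_is_balanced(exp1_design):
    s = BeliefState()
    for t in exp1_design.trials:
        s = update_belief(s, t)
    assert (s.n_confirmed, s.n_disconfirmed) == (6, 6)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(c=st.integers(0, 60), d=st.integers(0, 60))
def test_mu_moves_with_each_update(c, d):
    s = BeliefState(c, d)
    up = update_belief(s, make_trial(1, True, True))
    down = update_belief(s, make_trial(1, True, False))
    assert up.mu > s.mu > down.mu


def test_trace_first_predictive_trial_uses_the_prior():
    d = make_design("NDN", language=Language.EN_L2)
    trace = compute_trace([d], "en")
    assert trace.records[1].mu_before == 0.5
    assert trace.records[1].ic == pytest.approx(0.5 * 0.96)
    assert trace.records[0].ic == 0.0 and trace.records[2].ic == 0.0


def test_trace_ic_is_mu_times_pe_exactly(session_phases):
    trace = compute_trace(session_phases, "en", carry_over=True)
    for r in trace.records:
        assert r.ic == r.mu_before * r.pe


def test_carry_over_enters_experiment2_at_13_over_20(session_phases):
    trace = compute_trace(session_phases, Language.DE_L1, carry_over=True)
    exp2 = [r for r in trace.records if r.phase is Phase.EXPERIMENT2]
    assert exp2[0].mu_before == pytest.approx(0.65)
    first_d = next(r for r in exp2 if r.predictive_cue and not r.repeated_noun)
    # mu may have moved since phase entry, but if the first predictive trial
    # of experiment 2 is disconfirmed its cost is 0.65 * 0.92
    if first_d is next(r for r in exp2 if r.predictive_cue):
        assert first_d.ic == pytest.approx(0.65 * 0.92)


def test_out_of_order_phases_rejected(session_phases):
    exp1, training, exp2 = session_phases
    with pytest.raises(ValueError):
        compute_trace([exp2, training, exp1], "en", carry_over=True)
    # without carry-over any order is fine
    compute_trace([exp2, exp1], "en", carry_over=False)


def test_trace_is_order_dependent_but_final_state_is_not():
    d1 = make_design("CDCDCD")
    d2 = make_design("DDDCCC")
    t1 = compute_trace([d1], "en")
    t2 = compute_trace([d2], "en")
    assert t1.final_state == t2.final_state
    assert [r.ic for r in t1.records] != [r.ic for r in t2.records]


def test_ic_bounded_by_disconfirmed_pe(session_phases):
    trace = compute_trace(session_phases, "en", carry_over=True)
    for r in trace.records:
        assert 0.0 <= r.ic <= 0.96


def test_no_carry_over_across_languages_by_default(exp1_design):
    # each language's trace starts from the uniform prior independently
    t_en = compute_trace([exp1_design], "en")
    t_de = compute_trace([exp1_design], "de")
    assert t_en.records[0].mu_before == t_de.records[0].mu_before == 0.5


def test_trace_frame_round_trip(exp1_trace):
    frame = trace_to_frame(exp1_trace)
    assert len(frame) == 48
    assert (frame["ic"] == frame["mu_before"] * frame["pe"]).all()


def test_custom_pe_config_overrides_defaults():
    cfg = PEConfig(pe_confirmed={Language.EN_L2: 0.1, Language.DE_L1: 0.1},
                   pe_disconfirmed={Language.EN_L2: 0.9, Language.DE_L1: 0.9})
    t = make_trial(1, True, False)
    assert prediction_error(t, "en", cfg) == 0.9
    with pytest.raises(ValueError):
        PEConfig(pe_nocue=1.5)
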