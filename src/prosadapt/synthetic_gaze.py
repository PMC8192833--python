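"""Synthetic visual-world gaze data with known ground-truth effects.

Emulates 60 Hz AOI-coded fixation streams aligned to the onset of the second
instruction's noun, for six on-screen objects.  The target-fixation
probability at sample time ``t`` (ms from noun onset) follows a logistic
model whose terms mirror the analysis predictors:

    logit p(t) = base_intercept + base_slope * t/100
                 + fac_effect * [cue & repeated noun]
                 + ic_weight * IC(trial)
                 + trial_drift * z(trial number)
                 + b0_participant + bcue_participant * [cue]

so facilitation raises looks to the target on confirmed predictive trials
and a negative ``ic_weight`` suppresses them in proportion to the trial's
modeled inhibition cost.  Non-target probability mass is split between the
five other objects (uniformly) and an off-screen share.

Two sampling modes are provided.  ``independent`` draws every sample as an
independent Bernoulli/categorical event — exactly the data-generating
process assumed by the mixed-logit likelihood, so it is the mode used for
calibration and recovery studies.  ``markov`` holds the current AOI and
re-draws it only at fixation switches with hazard ``dt / dwell_mean_ms``,
giving realistically autocorrelated dwells for robustness checks.

Track loss marks samples as ``lost`` independently at a configurable rate;
participants whose loss exceeds an exclusion threshold (default 20%, the
study's participant-exclusion rule) can be flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .adaptation import InhibitionTrace
from .design import ExperimentDesign, TrialSpec

__all__ = [
    "GenerativeParams",
    "OBJECT_AOIS",
    "AOI_LEVELS",
    "sample_times",
    "target_probability",
    "simulate_trial",
    "simulate_dataset",
    "inject_track_loss",
    "participant_track_loss",
    "calibration_params",
]

#: the six pictured objects (AOIs entering the analysis denominator)
OBJECT_AOIS = ("target", "other1", "other2", "other3", "other4", "other5")
AOI_LEVELS = OBJECT_AOIS + ("offscreen", "lost")


@dataclass(frozen=True)
class GenerativeParams:
    """Ground-truth parameters of the gaze simulator.

    All effect parameters are on the logit scale.  Defaults describe a
    plausible mid-window visual-world profile: target looks a little below
    0.5 and rising through the noun window, a moderate facilitation boost on
    confirmed predictive trials, and an inhibition weight of -2 so that a
    unit of modeled cost roughly halves the target-fixation odds twice over.
    """

    base_intercept: float = -0.4     # logit of target fixation at noun onset
    base_slope: float = 0.15         # logit change per 100 ms
    fac_effect: float = 0.4          # boost on cue & repeated-noun trials
    ic_weight: float = -2.0          # per unit inhibition cost
    trial_drift: float = -0.1        # per SD of trial number
    sd_participant_intercept: float = 0.5
    sd_participant_cue_slope: float = 0.3
    sampling_rate: float = 60.0      # Hz
    epoch_start_ms: int = -200
    epoch_end_ms: int = 800
    offscreen_share: float = 0.1     # share of non-target mass off screen
    dwell_mean_ms: float = 250.0     # mean fixation dwell (markov mode)
    trackloss_rate: float = 0.05
    mode: str = "independent"        # "independent" | "markov"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.sd_participant_intercept < 0 or self.sd_participant_cue_slope < 0:
            raise ValueError("random-effect standard deviations must be >= 0")
        if not 0.0 <= self.trackloss_rate < 1.0:
            raise ValueError("trackloss_rate must lie in [0, 1)")
        if not 0.0 <= self.offscreen_share < 1.0:
            raise ValueError("offscreen_share must lie in [0, 1)")
        if self.mode not in ("independent", "markov"):
            raise ValueError("mode must be 'independent' or 'markov'")


def calibration_params(**overrides) -> GenerativeParams:
    """Likelihood-true configuration for calibration / recovery studies.

    Independent-sample mode with every systematic effect switched off except
    those explicitly overridden, no within-window time trend, no track loss,
    and a participant random intercept only.  This is the configuration under
    which the mixed-logit model is exactly the data-generating process.
    """
    base = GenerativeParams(
        base_intercept=-0.4, base_slope=0.0, fac_effect=0.0, ic_weight=0.0,
        trial_drift=0.0, sd_participant_intercept=0.5,
        sd_participant_cue_slope=0.0, trackloss_rate=0.0,
        offscreen_share=0.0, mode="independent")
    return replace(base, **overrides)


def sample_times(params: GenerativeParams) -> np.ndarray:
    """Integer sample times (ms) on the device grid covering the epoch."""
    step = 1000.0 / params.sampling_rate
    k0 = int(np.ceil(params.epoch_start_ms / step - 1e-9))
    k1 = int(np.floor(params.epoch_end_ms / step + 1e-9))
    return np.rint(np.arange(k0, k1 + 1) * step).astype(int)


def _trial_number_z(trial_index: int, n_trials: int) -> float:
    idx = np.arange(1, n_trials + 1, dtype=float)
    sd = idx.std(ddof=0)
    return float((trial_index - idx.mean()) / sd)


def target_probability(trial: TrialSpec, ic: float,
                       participant_effects: Sequence[float],
                       params: GenerativeParams,
                       n_trials_in_phase: int = 48) -> np.ndarray:
    """Per-sample target-fixation probability p(t) for one trial."""
    t = sample_times(params).astype(float)
    b0, bcue = participant_effects
    eta = (params.base_intercept
           + params.base_slope * t / 100.0
           + params.fac_effect * float(trial.predictive_cue and trial.repeated_noun)
           + params.ic_weight * ic
           + params.trial_drift * _trial_number_z(trial.trial_index,
                                                  n_trials_in_phase)
           + b0 + bcue * float(trial.predictive_cue))
    p = expit(eta)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("degenerate target probability; check parameters")
    return p


def _aoi_matrix(p_target: np.ndarray, params: GenerativeParams) -> np.ndarray:
    """Per-sample probability over the 7 drawable AOIs (no 'lost')."""
    rest = 1.0 - p_target
    off = rest * params.offscreen_share
    other = rest * (1.0 - params.offscreen_share) / 5.0
    cols = [p_target] + [other] * 5 + [off]
    return np.column_stack(cols)


def simulate_trial(trial: TrialSpec, ic: float,
                   participant_effects: Sequence[float],
                   params: GenerativeParams,
                   rng: np.random.Generator,
                   n_trials_in_phase: int = 48) -> pd.DataFrame:
    """Simulate one trial's AOI sample stream.

    Returns a frame with columns ``time_ms`` and ``aoi``; track loss is not
    applied here (see :func:`inject_track_loss`).
    """
    times = sample_times(params)
    p = target_probability(trial, ic, participant_effects, params,
                           n_trials_in_phase)
    probs = _aoi_matrix(p, params)
    n = len(times)
    aoi_idx = np.empty(n, dtype=int)
    if params.mode == "independent":
        u = rng.random((n, 1))
        aoi_idx = (probs.cumsum(axis=1) < u).sum(axis=1)
    else:
        step_ms = 1000.0 / params.sampling_rate
        hazard = min(1.0, step_ms / params.dwell_mean_ms)
        current = rng.choice(7, p=probs[0])
        aoi_idx[0] = current
        switches = rng.random(n) < hazard
        for i in range(1, n):
            if switches[i]:
                current = rng.choice(7, p=probs[i])
            aoi_idx[i] = current
    labels = np.array(AOI_LEVELS[:7])
    return pd.DataFrame({"time_ms": times, "aoi": labels[aoi_idx]})


def simulate_dataset(designs: Sequence[ExperimentDesign],
                     traces: Sequence[InhibitionTrace] | InhibitionTrace,
                     params: GenerativeParams,
                     n_participants: int = 17,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a long-format gaze table for a cohort.

    ``designs`` lists the phases as experienced; ``traces`` supplies the
    per-trial inhibition costs, either one trace spanning all phases or one
    per design.  Participant random effects are drawn once per participant.
    Track loss is applied at ``params.trackloss_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if isinstance(traces, InhibitionTrace):
        traces = [traces] * len(designs)
    if len(traces) != len(designs):
        raise ValueError("need one trace (or one shared trace) per design")

    blocks: list[pd.DataFrame] = []
    for pid in range(1, n_participants + 1):
        b0 = rng.normal(0.0, params.sd_participant_intercept)
        bcue = rng.normal(0.0, params.sd_participant_cue_slope)
        for design, trace in zip(designs, traces):
            for trial in design.trials:
                ic = trace.ic_for(design.phase, trial.trial_index)
                samples = simulate_trial(trial, ic, (b0, bcue), params, rng,
                                         n_trials_in_phase=len(design))
                samples.insert(0, "participant_id", pid)
                samples.insert(1, "language", design.language.value)
                samples.insert(2, "phase", design.phase.value)
                samples.insert(3, "trial_index", trial.trial_index)
                samples.insert(4, "predictive_cue", trial.predictive_cue)
                samples.insert(5, "repeated_noun", trial.repeated_noun)
                samples.insert(6, "adjective_contrast",
                               trial.adjective_contrast.value)
                samples.insert(7, "included", trial.included)
                samples.insert(8, "ic", ic)
                blocks.append(samples)
    table = pd.concat(blocks, ignore_index=True)
    if params.trackloss_rate > 0:
        table = inject_track_loss(table, params.trackloss_rate, rng)
    return table


def simulate_window_counts(designs: Sequence[ExperimentDesign],
                           traces: Sequence[InhibitionTrace] | InhibitionTrace,
                           params: GenerativeParams,
                           n_participants: int = 17,
                           window: tuple[int, int] = (150, 450),
                           rng: np.random.Generator | None = None,
                           included_only: bool = True) -> pd.DataFrame:
    """Independent-mode simulation aggregated directly to in-window counts.

    Draws the same per-sample Bernoulli target/non-target events as
    ``simulate_dataset`` in independent mode (no track loss) but sums them to
    the per-trial response (y, n) inside the analysis window, skipping the
    long-format table.  Used by the calibration and recovery studies, where
    thousands of cohorts are simulated.
    """
    if params.mode != "independent":
        raise ValueError("count-level simulation is defined for independent mode")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if isinstance(traces, InhibitionTrace):
        traces = [traces] * len(designs)
    times = sample_times(params)
    in_win = (times >= window[0]) & (times < window[1])
    n_win = int(in_win.sum())

    rows = []
    for pid in range(1, n_participants + 1):
        b0 = rng.normal(0.0, params.sd_participant_intercept)
        bcue = rng.normal(0.0, params.sd_participant_cue_slope)
        for design, trace in zip(designs, traces):
            trials = [t for t in design.trials
                      if t.included or not included_only]
            probs = np.vstack([
                target_probability(t, trace.ic_for(design.phase, t.trial_index),
                                   (b0, bcue), params, len(design))[in_win]
                for t in trials
            ])
            y = (rng.random(probs.shape) < probs).sum(axis=1)
            for t, yi in zip(trials, y):
                rows.append({
                    "participant_id": pid,
                    "language": design.language.value,
                    "phase": design.phase.value,
                    "trial_index": t.trial_index,
                    "predictive_cue": t.predictive_cue,
                    "repeated_noun": t.repeated_noun,
                    "ic": trace.ic_for(design.phase, t.trial_index),
                    "y": int(yi),
                    "n": n_win,
                })
    return pd.DataFrame(rows)


def inject_track_loss(table: pd.DataFrame, rate: float,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Mark samples as lost independently at ``rate``.

    Returns a copy; already-lost samples stay lost.  Participant-level
    exclusion flags are computed by :func:`participant_track_loss`.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return table
    out = table.copy()
    lost = rng.random(len(out)) < rate
    out.loc[lost, "aoi"] = "lost"
    return out


def participant_track_loss(table: pd.DataFrame,
                           threshold: float = 0.2) -> pd.DataFrame:
    """Per-participant track-loss fraction with an exclusion flag.

    The default threshold mirrors the study's rule of excluding participants
    with more than 20% missing samples.
    """
    frac = (table.assign(lost=table["aoi"].eq("lost"))
            .groupby("participant_id")["lost"].mean())
    return pd.DataFrame({
        "trackloss_fraction": frac,
        "excluded": frac > threshold,
    }).reset_index()
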