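"""Experimental and training trial-sequence generation.

The study's visual-world experiments pair two click instructions per trial.
The second instruction carries one of three prosodic patterns — a contrastive
L+H* pitch accent on the color adjective (the predictive cue), an L+H* on the
noun, or no L+H* — and its noun either repeats the first instruction's noun
or is novel.  Each experimental phase has 48 trials; the 36 trials whose two
instructions use *different* color adjectives enter the analyses, the 12
repeated-adjective trials are fillers.  A 24-trial training phase contains
only felicitous trials so that every adjective L+H* is confirmed.

Published constraints reproduced here:

* experimental cell counts (cue x repeated-noun): 6 / 6 / 6 / 18, the 18
  no-cue novel-noun trials splitting 12 with no L+H* and 6 with a noun L+H*;
* one quarter of the trials in every phase carry the adjective L+H*;
* no two consecutive trials share a prosodic pattern (pseudorandomization);
* picture sets rotate across blocks of six trials (Latin-square style).

Exact published trial orders are not available, so orders are drawn by
rejection sampling: shuffle, test the adjacency constraint, retry.  German
and English sessions used the same trial order, so the order depends only on
``(seed, phase)``; the language is carried as a label.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Language",
    "Phase",
    "Prosody",
    "AdjectiveContrast",
    "TrialSpec",
    "ExperimentDesign",
    "build_experiment_design",
    "build_training_design",
    "apply_inclusion_filter",
    "design_to_frame",
    "design_from_frame",
    "design_to_json",
    "design_from_json",
]

MAX_SHUFFLE_ATTEMPTS = 10_000


class Language(str, enum.Enum):
    """Session language: German is the participants' L1, English their L2."""

    DE_L1 = "de"
    EN_L2 = "en"


class Phase(str, enum.Enum):
    EXPERIMENT1 = "experiment1"
    TRAINING = "training"
    EXPERIMENT2 = "experiment2"


#: chronological order of phases within one language session
PHASE_ORDER = (Phase.EXPERIMENT1, Phase.TRAINING, Phase.EXPERIMENT2)


class Prosody(str, enum.Enum):
    LH_ADJECTIVE = "LH_adjective"
    LH_NOUN = "LH_noun"
    NO_LH = "no_LH"


class AdjectiveContrast(str, enum.Enum):
    DIFFERENT = "different"
    REPEATED = "repeated"


@dataclass(frozen=True)
class TrialSpec:
    """One two-instruction trial.

    ``predictive_cue`` is true iff the second instruction's adjective carries
    the L+H* accent; ``included`` is true iff the two instructions use
    different color adjectives (the analysis inclusion rule).
    """

    trial_index: int
    predictive_cue: bool
    repeated_noun: bool
    prosody: Prosody
    adjective_contrast: AdjectiveContrast
    picture_set: int
    included: bool

    def __post_init__(self) -> None:
        if self.predictive_cue != (self.prosody is Prosody.LH_ADJECTIVE):
            raise ValueError(
                "predictive_cue must hold exactly when prosody is LH_adjective"
            )
        if self.included != (self.adjective_contrast is AdjectiveContrast.DIFFERENT):
            raise ValueError(
                "included must hold exactly when the adjectives differ"
            )
        if not 1 <= self.picture_set <= 6:
            raise ValueError("picture_set must be in 1..6")


@dataclass(frozen=True)
class ExperimentDesign:
    language: Language
    phase: Phase
    trials: tuple[TrialSpec, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


def _make(cue: bool, repeated: bool, prosody: Prosody,
          contrast: AdjectiveContrast) -> dict:
    return {
        "predictive_cue": cue,
        "repeated_noun": repeated,
        "prosody": prosody,
        "adjective_contrast": contrast,
        "included": contrast is AdjectiveContrast.DIFFERENT,
    }


def _experiment_pool() -> list[dict]:
    """The 48-trial experimental composition (cell counts 6/6/6/18 + 12 fillers)."""
    diff = AdjectiveContrast.DIFFERENT
    rep = AdjectiveContrast.REPEATED
    pool: list[dict] = []
    pool += [_make(True, True, Prosody.LH_ADJECTIVE, diff)] * 6
    pool += [_make(True, False, Prosody.LH_ADJECTIVE, diff)] * 6
    pool += [_make(False, True, Prosody.NO_LH, diff)] * 6
    pool += [_make(False, False, Prosody.NO_LH, diff)] * 12
    pool += [_make(False, False, Prosody.LH_NOUN, diff)] * 6
    # felicitous repeated-adjective fillers: split across the two non-cue
    # patterns so the adjective-L+H* share stays at 0.25
    pool += [_make(False, False, Prosody.LH_NOUN, rep)] * 6
    pool += [_make(False, False, Prosody.NO_LH, rep)] * 6
    return pool


def _training_pool() -> list[dict]:
    """The 24-trial training composition: felicitous trials only."""
    diff = AdjectiveContrast.DIFFERENT
    rep = AdjectiveContrast.REPEATED
    pool: list[dict] = []
    pool += [_make(False, False, Prosody.NO_LH, diff)] * 12
    pool += [_make(False, False, Prosody.LH_NOUN, rep)] * 6
    pool += [_make(True, True, Prosody.LH_ADJECTIVE, diff)] * 6
    return pool


def _feasible(counts: dict, prev) -> bool:
    """Can the remaining multiset be ordered with no equal neighbours,
    starting with a category other than ``prev``?"""
    m = sum(counts.values())
    if m == 0:
        return True
    cap = (m + 1) // 2
    if max(counts.values()) > cap:
        return False
    if m % 2 == 1 and prev is not None and counts.get(prev, 0) == cap:
        # prev would have to occupy the first slot as well
        return False
    return True


def _order_pool(pool: list[dict], rng: np.random.Generator) -> list[dict]:
    """Random order with no two consecutive trials sharing a prosody.

    Trials are placed sequentially: at each position one of the remaining
    trials is drawn uniformly among those whose prosodic pattern differs
    from the previous trial's and leaves the remainder orderable (a counting
    feasibility check).  Half of an experimental phase carries the no-L+H*
    pattern, so plain shuffle-and-reject is hopeless at this density; the
    look-ahead makes every draw completable.
    """
    by_cat: dict[Prosody, list[dict]] = {}
    for item in pool:
        by_cat.setdefault(item["prosody"], []).append(item)
    for items in by_cat.values():
        rng.shuffle(items)

    counts = {cat: len(items) for cat, items in by_cat.items()}
    ordered: list[dict] = []
    prev = None
    for _ in range(len(pool)):
        candidates = []
        for cat, c in counts.items():
            if c == 0 or cat is prev:
                continue
            counts[cat] -= 1
            if _feasible(counts, cat):
                candidates.append(cat)
            counts[cat] += 1
        if not candidates:
            raise RuntimeError(
                "prosody adjacency constraint unsatisfiable for this trial "
                "composition (internal bug)")
        weights = np.array([counts[c] for c in candidates], float)
        cat = candidates[rng.choice(len(candidates), p=weights / weights.sum())]
        counts[cat] -= 1
        ordered.append(by_cat[cat].pop())
        prev = cat
    return ordered


def _assign_picture_sets(n_trials: int) -> list[int]:
    """Rotate the six picture sets across consecutive blocks of six trials."""
    sets = []
    for i in range(n_trials):
        block, pos = divmod(i, 6)
        sets.append((pos + block) % 6 + 1)
    return sets


def _build(language: Language, phase: Phase, pool: list[dict],
           seed: int) -> ExperimentDesign:
    # order is a function of (seed, phase) only: both language versions of
    # the study used the same trial order
    rng = np.random.default_rng([seed, list(Phase).index(phase)])
    ordered = _order_pool(pool, rng)
    sets = _assign_picture_sets(len(ordered))
    trials = tuple(
        TrialSpec(trial_index=i + 1, picture_set=sets[i], **spec)
        for i, spec in enumerate(ordered)
    )
    return ExperimentDesign(language=language, phase=phase,
                            trials=trials, seed=seed)


def build_experiment_design(language: Language | str, phase: Phase | str,
                            seed: int) -> ExperimentDesign:
    """Generate one 48-trial experimental phase.

    Parameters
    ----------
    language
        ``Language.DE_L1`` or ``Language.EN_L2`` (or their string values).
    phase
        ``Phase.EXPERIMENT1`` or ``Phase.EXPERIMENT2``.
    seed
        Any integer; fixes the trial order deterministically.
    """
    language = Language(language)
    phase = Phase(phase)
    if phase is Phase.TRAINING:
        raise ValueError("use build_training_design for the training phase")
    return _build(language, phase, _experiment_pool(), seed)


def build_training_design(language: Language | str, seed: int) -> ExperimentDesign:
    """Generate the 24-trial training phase (felicitous trials only)."""
    return _build(Language(language), Phase.TRAINING, _training_pool(), seed)


def apply_inclusion_filter(design: ExperimentDesign) -> ExperimentDesign:
    """Keep only trials whose two instructions use different color adjectives.

    Order and original ``trial_index`` values are preserved; the operation is
    idempotent.
    """
    kept = tuple(t for t in design.trials if t.included)
    return replace(design, trials=kept)


# ---------------------------------------------------------------------------
# tabular / JSON round trip

_COLUMNS = ["trial_index", "language", "phase", "predictive_cue",
            "repeated_noun", "prosody", "adjective_contrast", "picture_set",
            "included"]


def design_to_frame(design: ExperimentDesign) -> pd.DataFrame:
    rows = [
        {
            "trial_index": t.trial_index,
            "language": design.language.value,
            "phase": design.phase.value,
            "predictive_cue": t.predictive_cue,
            "repeated_noun": t.repeated_noun,
            "prosody": t.prosody.value,
            "adjective_contrast": t.adjective_contrast.value,
            "picture_set": t.picture_set,
            "included": t.included,
        }
        for t in design.trials
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def design_from_frame(frame: pd.DataFrame, seed: int = -1) -> ExperimentDesign:
    if frame.empty:
        raise ValueError("cannot reconstruct a design from an empty table")
    language = Language(frame["language"].iloc[0])
    phase = Phase(frame["phase"].iloc[0])
    trials = tuple(
        TrialSpec(
            trial_index=int(r.trial_index),
            predictive_cue=bool(r.predictive_cue),
            repeated_noun=bool(r.repeated_noun),
            prosody=Prosody(r.prosody),
            adjective_contrast=AdjectiveContrast(r.adjective_contrast),
            picture_set=int(r.picture_set),
            included=bool(r.included),
        )
        for r in frame.itertuples()
    )
    return ExperimentDesign(language=language, phase=phase, trials=trials,
                            seed=seed)


def design_to_json(design: ExperimentDesign) -> str:
    payload = {
        "language": design.language.value,
        "phase": design.phase.value,
        "seed": design.seed,
        "trials": design_to_frame(design).to_dict(orient="records"),
    }
    return json.dumps(payload, indent=1)


def design_from_json(text: str) -> ExperimentDesign:
    payload = json.loads(text)
    frame = pd.DataFrame(payload["trials"], columns=_COLUMNS)
    return design_from_frame(frame, seed=payload.get("seed", -1))
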