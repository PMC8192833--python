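"""Small constructors shared across test modules."""

from prosadapt.design import (AdjectiveContrast, ExperimentDesign, Language,
                              Phase, Prosody, TrialSpec)


def make_trial(idx, cue, repeated):
    return TrialSpec(
        trial_index=idx, predictive_cue=cue, repeated_noun=repeated,
        prosody=Prosody.LH_ADJECTIVE if cue else Prosody.NO_LH,
        adjective_contrast=AdjectiveContrast.DIFFERENT,
        picture_set=1, included=True)


def make_design(outcomes, phase=Phase.EXPERIMENT1, language=Language.EN_L2):
    """outcomes: string of 'C' (cue+repeated), 'D' (cue+novel), 'N' (no cue)."""
    trials = tuple(
        make_trial(i + 1, o != "N", o == "C") for i, o in enumerate(outcomes))
    return ExperimentDesign(language=language, phase=phase, trials=trials,
                            seed=0)
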