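"""End-to-end orchestration: design -> trace -> simulate -> transform ->
fit -> report.

A run is described by a :class:`RunConfig` (loadable from YAML).  For each
requested language the pipeline generates the three phases (experiment 1,
training, experiment 2), computes the carried-over inhibition-cost trace,
simulates a gaze cohort, extracts the analysis window, fits Models A/B/C per
experimental phase, decomposes the Cue x Repeated Noun interaction, compares
Model C with and without Inhibition Cost, and writes tables, figures and a
qualitative summary grid.  Every output directory is stamped with the config
hash and the seeds consumed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import adaptation, design as design_mod, gaze_io, inference, \
    synthetic_gaze
from .adaptation import PEConfig, compute_trace, trace_to_frame
from .design import (Language, Phase, apply_inclusion_filter,
                     build_experiment_design, build_training_design,
                     design_to_frame)
from .gaze_io import (WindowSpec, aggregate_trial_counts, extract_window,
                      proportion_curves)
from .synthetic_gaze import GenerativeParams, simulate_dataset

log = logging.getLogger("prosadapt")

__all__ = ["RunConfig", "run_pipeline", "load_config"]

ALPHA = 0.05


@dataclass
class RunConfig:
    languages: tuple[str, ...] = ("de", "en")
    design_seed: int = 1
    generator_seed: int = 2
    n_participants: int = 17
    params: GenerativeParams = field(default_factory=GenerativeParams)
    window: WindowSpec = field(default_factory=WindowSpec)
    response_mode: str = "per_trial_binomial"
    trackloss_threshold: float = 0.2
    make_plots: bool = True
    outdir: str = "prosadapt_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    params = GenerativeParams(**raw.pop("params", {}))
    window = WindowSpec(**raw.pop("window", {}))
    langs = tuple(raw.pop("languages", ("de", "en")))
    return RunConfig(languages=langs, params=params, window=window, **raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as exc:   # noqa: BLE001 - relabelled and re-raised
                raise StageError(name, exc) from exc
            log.info("stage %-10s %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _star(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 \
        else "n.s."


@_stage("design")
def _make_designs(language: Language, seed: int, outdir: Path):
    phases = [
        build_experiment_design(language, Phase.EXPERIMENT1, seed),
        build_training_design(language, seed),
        build_experiment_design(language, Phase.EXPERIMENT2, seed),
    ]
    for d in phases:
        design_to_frame(d).to_csv(
            outdir / f"design_{language.value}_{d.phase.value}.tsv",
            sep="\t", index=False)
    return phases


@_stage("trace")
def _make_trace(phases, language, outdir: Path, make_plots: bool):
    trace = compute_trace(phases, language, carry_over=True)
    trace_to_frame(trace).to_csv(
        outdir / f"trace_{language.value}.tsv", sep="\t", index=False)
    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        exp1 = adaptation.InhibitionTrace(
            trace.language,
            tuple(r for r in trace.records if r.phase is Phase.EXPERIMENT1),
            trace.final_state)
        exp2 = adaptation.InhibitionTrace(
            trace.language,
            tuple(r for r in trace.records if r.phase is Phase.EXPERIMENT2),
            trace.final_state)
        ax = adaptation.plot_trace({"Experiment 1": exp1,
                                    "Experiment 2": exp2})
        ax.figure.savefig(outdir / f"ic_trajectory_{language.value}.png",
                          dpi=120)
        import matplotlib.pyplot as plt
        plt.close(ax.figure)
    return trace


@_stage("simulate")
def _simulate(phases, trace, config: RunConfig, language, outdir: Path):
    import numpy as np
    params = dataclasses.replace(config.params, seed=config.generator_seed)
    rng = np.random.default_rng([config.generator_seed,
                                 list(Language).index(language)])
    table = simulate_dataset(phases, trace, params,
                             n_participants=config.n_participants, rng=rng)
    gaze_io.write_gaze_table(table,
                             outdir / f"gaze_{language.value}.tsv")
    flags = synthetic_gaze.participant_track_loss(
        table, config.trackloss_threshold)
    flags.to_csv(outdir / f"trackloss_{language.value}.tsv", sep="\t",
                 index=False)
    return table


@_stage("transform")
def _transform(table, config: RunConfig, language, outdir: Path):
    windowed = extract_window(table, config.window)
    responses = aggregate_trial_counts(windowed)
    responses.to_csv(outdir / f"responses_{language.value}.tsv", sep="\t",
                     index=False)
    if config.make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        for phase in (Phase.EXPERIMENT1, Phase.EXPERIMENT2):
            curves = proportion_curves(
                table[(table["phase"] == phase.value) & table["included"]])
            if curves.empty:
                continue
            ax = gaze_io.plot_proportion_curves(curves, window=config.window)
            ax.set_title(f"{language.value} {phase.value}")
            ax.figure.savefig(
                outdir / f"curves_{language.value}_{phase.value}.png",
                dpi=120)
            plt.close(ax.figure)
    return responses


@_stage("fit")
def _fit(responses, config: RunConfig, language, outdir: Path):
    results = {}
    for phase in (Phase.EXPERIMENT1, Phase.EXPERIMENT2):
        sub = responses[responses["phase"] == phase.value]
        if "included" in sub.columns:
            sub = sub[sub["included"].astype(bool)]
        if sub.empty:
            continue
        key = f"{language.value}_{phase.value}"
        fits = {
            "A": inference.fit_model_A(sub, config.response_mode),
            "B": inference.fit_model_B(sub, response_mode=config.response_mode),
            "C": inference.fit_model_C(sub, response_mode=config.response_mode),
        }
        comparison = inference.compare_with_without_IC(
            sub, response_mode=config.response_mode)
        try:
            subsets = inference.decompose_interaction(sub,
                                                      config.response_mode)
        except ValueError:
            subsets = {}
        for name, fit in {**fits, **subsets}.items():
            with open(outdir / f"fit_{key}_{name}.json", "w") as fh:
                fh.write(fit.to_json())
        with open(outdir / f"comparison_{key}.json", "w") as fh:
            fh.write(comparison.to_json())
        results[key] = {"fits": fits, "subsets": subsets,
                        "comparison": comparison}
    return results


@_stage("report")
def _report(all_results: dict, config: RunConfig, outdir: Path):
    lines = ["# Summary of the main analysis results", "",
             f"config hash: {config.config_hash}; "
             f"design seed {config.design_seed}; "
             f"generator seed {config.generator_seed}", "",
             "| Language x Phase | Cue x Repeated (A) | IC alone (B) | "
             "IC beyond conditions (C vs without) | Verdict |",
             "|---|---|---|---|---|"]
    for key, res in all_results.items():
        a = res["fits"]["A"].term("cue_c:rep_c")
        b = res["fits"]["B"].term("ic_c")
        comp = res["comparison"]
        ic_detected = b["p"] < ALPHA and b["estimate"] < 0
        verdict = ("inhibition cost detected" if ic_detected
                   else "no inhibition detected")
        lines.append(
            f"| {key} | {a['estimate']:+.2f} ({_star(a['p'])}) "
            f"| {b['estimate']:+.2f} ({_star(b['p'])}) "
            f"| LR p={comp.p:.3g}, dAIC={comp.delta_aic:+.1f} "
            f"| {verdict} |")
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
    return lines


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every configured language; returns fit results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.json").write_text(
        json.dumps({"config": config.to_dict(),
                    "config_hash": config.config_hash}, indent=1,
                   default=str))
    all_results: dict = {}
    for lang in config.languages:
        language = Language(lang)
        phases = _make_designs(language, config.design_seed, outdir)
        trace = _make_trace(phases, language, outdir, config.make_plots)
        table = _simulate(phases, trace, config, language, outdir)
        responses = _transform(table, config, language, outdir)
        all_results.update(_fit(responses, config, language, outdir))
    _report(all_results, config, outdir)
    return all_results
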