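"""Gaze-table data model and transformations.

A gaze table is a long-format frame of AOI-coded samples, one row per
(participant, phase, trial, sample time), with ``time_ms`` relative to the
onset of the second instruction's noun.  This module extracts the analysis
window, aggregates samples to the mixed-logit response, and computes
proportion-of-looks curves.

The analysis window runs from 150 to 450 ms after noun onset — offset by
roughly the saccade-programming latency, so it covers approximately the
first 300 ms of processing the noun.  The window is half-open, [150, 450),
so no sample can fall in two adjacent windows.  The response for a trial is
y / n where y counts in-window samples on the target object and n counts
in-window samples on any of the six pictured objects; off-screen and lost
samples belong to neither and are excluded from both counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_gaze import OBJECT_AOIS

__all__ = [
    "WindowSpec",
    "extract_window",
    "aggregate_trial_counts",
    "proportion_curves",
    "read_gaze_table",
    "write_gaze_table",
    "plot_proportion_curves",
]

TRIAL_KEYS = ["participant_id", "language", "phase", "trial_index"]
CONDITION_COLS = ["predictive_cue", "repeated_noun"]


@dataclass(frozen=True)
class WindowSpec:
    """Half-open analysis window [start_ms, end_ms) after noun onset."""

    start_ms: int = 150
    end_ms: int = 450

    def __post_init__(self) -> None:
        if self.start_ms >= self.end_ms:
            raise ValueError("window start must precede its end")


def extract_window(table: pd.DataFrame,
                   window: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Retain samples with start_ms <= time_ms < end_ms."""
    mask = (table["time_ms"] >= window.start_ms) & \
           (table["time_ms"] < window.end_ms)
    return table.loc[mask].reset_index(drop=True)


def aggregate_trial_counts(table: pd.DataFrame,
                           extra_cols: tuple[str, ...] = ("ic", "included")
                           ) -> pd.DataFrame:
    """Collapse a (windowed) table to one row per trial.

    Returns columns y (target samples), n (six-object samples), the trial
    keys, the condition columns, any ``extra_cols`` present (constant within
    trial, e.g. the inhibition cost), and ``valid`` — False for trials with
    n = 0, which have no defined proportion and are excluded from modelling.
    """
    carried = [c for c in list(CONDITION_COLS) + list(extra_cols)
               if c in table.columns]
    g = table.assign(
        _target=table["aoi"].eq("target"),
        _object=table["aoi"].isin(OBJECT_AOIS),
    ).groupby(TRIAL_KEYS, sort=True, observed=True)
    out = g.agg(**{
        "y": ("_target", "sum"),
        "n": ("_object", "sum"),
        **{c: (c, "first") for c in carried},
    }).reset_index()
    out["valid"] = out["n"] > 0
    return out


def proportion_curves(table: pd.DataFrame, bin_ms: float | None = None
                      ) -> pd.DataFrame:
    """Mean target proportion over time per cue x repeated-noun condition.

    Within each condition and time bin the statistic is the mean over trials
    of the per-trial proportion (target samples / six-object samples); trials
    contributing no object sample to a bin are skipped, and bins with no data
    are absent from the output rather than zero.  The default bin is one
    device sample.
    """
    df = table[table["aoi"].isin(OBJECT_AOIS + ("offscreen", "lost"))].copy()
    if bin_ms is None:
        df["time_bin"] = df["time_ms"]
    else:
        df["time_bin"] = (df["time_ms"] // bin_ms).astype(int) * bin_ms
    df["_target"] = df["aoi"].eq("target")
    df["_object"] = df["aoi"].isin(OBJECT_AOIS)
    per_trial = (df.groupby(CONDITION_COLS + ["time_bin"] + TRIAL_KEYS,
                            observed=True)[["_target", "_object"]]
                 .sum().reset_index())
    per_trial = per_trial[per_trial["_object"] > 0]
    per_trial["prop"] = per_trial["_target"] / per_trial["_object"]
    curves = (per_trial.groupby(CONDITION_COLS + ["time_bin"], observed=True)
              ["prop"].mean().reset_index()
              .rename(columns={"prop": "target_proportion"}))
    return curves


def plot_proportion_curves(curves: pd.DataFrame, ax=None,
                           window: WindowSpec = WindowSpec()):
    """Plot per-condition proportion-of-looks curves, analysis window shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    labels = {
        (True, True): "cue, repeated noun",
        (True, False): "cue, novel noun",
        (False, True): "no cue, repeated noun",
        (False, False): "no cue, novel noun",
    }
    for (cue, rep), grp in curves.groupby(CONDITION_COLS, observed=True):
        ax.plot(grp["time_bin"], grp["target_proportion"],
                label=labels.get((bool(cue), bool(rep))))
    ax.axvspan(window.start_ms, window.end_ms, alpha=0.15, color="gray")
    ax.set_xlabel("Time from noun onset (ms)")
    ax.set_ylabel("Proportion of looks to target")
    ax.legend(fontsize=8)
    return ax


# ---------------------------------------------------------------------------
# file dialect: tab-delimited UTF-8 with header; reader also accepts commas

def write_gaze_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gaze_table(path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep)
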