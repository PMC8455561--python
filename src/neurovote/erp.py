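"""Condition averaging, N400 window amplitudes and the congruency ANOVAs.

The congruency hypothesis: the N400 — a posterior negativity 300-600 ms
after the critical word — is larger for survey items that contradict the
participant's political attitudes (populist items for mainstream voters,
non-populist items for populist voters).  It is tested with a mixed ANOVA
(Voting Behavior between; Item Type x Issue Dimension x Electrode within),
followed up per dimension and per voting group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .containers import EpochArray
from .errors import ParameterError
from .stats import mixed_anova

__all__ = ["ERPAverages", "average_conditions", "extract_n400",
           "n400_differential", "n400_hypothesis_suite"]


@dataclass
class ERPAverages:
    """Per participant x dimension x item-type average waveforms."""

    waveforms: dict[tuple[str, str, str], np.ndarray]  # key -> (ch x time) uV
    n_trials: dict[tuple[str, str, str], int]
    channels: tuple[str, ...]
    times: np.ndarray


def average_conditions(epochs: dict[str, EpochArray],
                       trials: pd.DataFrame,
                       participant_ids: list[str] | None = None,
                       min_trials: int = 1) -> ERPAverages:
    """Arithmetic mean over artifact-free trials per condition cell.

    Cells with fewer than ``min_trials`` clean trials are omitted (never
    zero-filled).  ``participant_ids`` restricts to the retained sample.
    """
    ids = list(epochs) if participant_ids is None else list(participant_ids)
    if not ids:
        raise ParameterError("no participants to average")
    ref = epochs[ids[0]]
    waveforms: dict[tuple[str, str, str], np.ndarray] = {}
    counts: dict[tuple[str, str, str], int] = {}
    for pid in ids:
        e = epochs[pid]
        if e.channels != ref.channels:
            raise ParameterError(f"channel montage differs for {pid}")
        t = trials[trials["participant_id"] == pid].sort_values("trial_index")
        if len(t) != e.n_trials:
            raise ParameterError(f"trial table does not align with epochs for {pid}")
        clean = ~t["artifact"].to_numpy()
        dims = t["dimension"].to_numpy()
        itypes = t["item_type"].to_numpy()
        for dim in pd.unique(dims):
            for item_type in pd.unique(itypes):
                sel = clean & (dims == dim) & (itypes == item_type)
                n = int(sel.sum())
                if n >= min_trials and n > 0:
                    waveforms[(pid, dim, item_type)] = e.data[:, :, sel].mean(axis=2)
                    counts[(pid, dim, item_type)] = n
    return ERPAverages(waveforms, counts, ref.channels, ref.times.copy())


def extract_n400(averages: ERPAverages, config: AnalysisConfig) -> pd.DataFrame:
    """Mean amplitude over the N400 window per cell x posterior electrode.

    Returns a long table (participant_id, dimension, item_type, electrode,
    amplitude) over the 12 posterior electrodes, with the time mean taken
    over the half-open ``[300, 600)`` ms window.
    """
    lo, hi = config.n400_window
    tmask = (averages.times >= lo) & (averages.times < hi)
    if not tmask.any():
        raise ParameterError(f"window [{lo}, {hi}) ms contains no samples")
    missing = [c for c in config.n400_channels if c not in averages.channels]
    if missing:
        raise ParameterError(f"montage lacks N400 channel(s): {missing}")
    ch_idx = {c: averages.channels.index(c) for c in config.n400_channels}
    rows = []
    for (pid, dim, item_type), wf in averages.waveforms.items():
        win = wf[:, tmask].mean(axis=1)
        for ch, i in ch_idx.items():
            rows.append((pid, dim, item_type, ch, float(win[i])))
    return pd.DataFrame(rows, columns=["participant_id", "dimension",
                                       "item_type", "electrode", "amplitude"])


def n400_differential(n400: pd.DataFrame, dimension: str = "economy",
                      electrode: str = "POz") -> pd.Series:
    """Per-participant differential amplitude (populist minus non-populist
    item waveform) at one electrode — the brain-based voting predictor."""
    sub = n400[(n400["dimension"] == dimension)
               & (n400["electrode"] == electrode)]
    wide = sub.pivot_table(index="participant_id", columns="item_type",
                           values="amplitude", observed=True)
    if "populist" not in wide or "non_populist" not in wide:
        raise ParameterError(
            f"no {dimension}/{electrode} amplitudes for both item types")
    diff = wide["populist"] - wide["non_populist"]
    diff.name = f"n400_{dimension}"
    return diff.dropna()


def n400_hypothesis_suite(n400: pd.DataFrame, participants: pd.DataFrame,
                          config: AnalysisConfig) -> dict:
    """Omnibus and follow-up ANOVAs for the N400 congruency hypothesis.

    Returns a dict with the omnibus table (Voting Behavior x Item Type x
    Dimension x Electrode), per-dimension follow-ups (Voting Behavior x
    Item Type, electrodes averaged) and, for the economy dimension,
    per-group Item Type follow-ups.
    """
    votes = participants.set_index("participant_id")["vote"]
    data = n400.copy()
    data["vote"] = data["participant_id"].map(votes)
    data = data[data["vote"].isin(["mainstream", "populist"])]
    if data.empty:
        raise ParameterError("no analysable participants in the N400 table")

    omnibus = mixed_anova(data, "amplitude", "participant_id", "vote",
                          ["item_type", "dimension", "electrode"])

    # electrode-mean scores for the follow-ups
    cellmean = (data.groupby(["participant_id", "vote", "dimension",
                              "item_type"], observed=True)["amplitude"]
                .mean().reset_index())
    followup_dimension = {
        dim: mixed_anova(cellmean[cellmean["dimension"] == dim], "amplitude",
                         "participant_id", "vote", ["item_type"])
        for dim in cellmean["dimension"].unique()
    }
    economy = cellmean[cellmean["dimension"] == "economy"]
    followup_group = {
        grp: mixed_anova(economy[economy["vote"] == grp], "amplitude",
                         "participant_id", None, ["item_type"])
        for grp in economy["vote"].unique()
    }
    return {"omnibus": omnibus, "followup_dimension": followup_dimension,
            "followup_group": followup_group}
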