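"""Deterministic epoch conditioning and exclusion bookkeeping.

The conditioning chain is band-pass filtering (zero-phase, 0.1-30 Hz by
default), re-referencing to the channel average, baseline correction over
the 100 ms pre-stimulus interval, and amplitude-threshold artifact flagging.
Participant exclusion proceeds in stages — vote-based filtering, the
14-epoch ERP rule, the 20-trial decoding rule and the missing-responses
rule — and every removal is logged with the rule that caused it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .config import AnalysisConfig
from .containers import (ANALYSIS_VOTES, DIMENSIONS, ITEM_TYPES, EpochArray,
                         check_participant_table, check_trial_table)
from .errors import FormatError, ParameterError

EXCLUSION_STAGES = ("vote_filter", "erp_min_trials", "mvpa_min_trials",
                    "behav_missing")


def bandpass_filter(epochs: EpochArray, low: float, high: float,
                    order: int = 4, hp_order: int = 1) -> EpochArray:
    """Zero-phase Butterworth band-pass along the time axis.

    The low-pass edge uses a Butterworth of ``order`` and the high-pass edge
    a gentle filter of ``hp_order`` (default 1, i.e. 12 dB/octave after the
    forward-backward pass).  A steep high-pass on short epochs smears late
    slow deflections backwards through the epoch — the classic ERP
    distortion — so the high-pass roll-off is deliberately shallow.
    ``low`` may be 0 for a pure low-pass.
    """
    nyq = epochs.sfreq / 2.0
    if not (0 <= low < high < nyq):
        raise ParameterError(
            f"band [{low}, {high}] Hz invalid for sfreq {epochs.sfreq} Hz")
    sos = signal.butter(order, high, btype="lowpass",
                        fs=epochs.sfreq, output="sos")
    if low > 0:
        sos_hp = signal.butter(hp_order, low, btype="highpass",
                               fs=epochs.sfreq, output="sos")
        sos = np.vstack([sos, sos_hp])
    out = epochs.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    return out


def rereference_average(epochs: EpochArray) -> EpochArray:
    """Subtract the instantaneous mean over channels from every channel."""
    if epochs.n_channels < 2:
        raise ParameterError("average reference requires at least 2 channels")
    out = epochs.copy()
    out.data -= out.data.mean(axis=0, keepdims=True)
    return out


def baseline_correct(epochs: EpochArray,
                     window: tuple[float, float] = (-100.0, 0.0)) -> EpochArray:
    """Subtract the per-channel, per-trial mean over the half-open baseline window."""
    lo, hi = window
    mask = (epochs.times >= lo) & (epochs.times < hi)
    if not mask.any():
        raise ParameterError(
            f"baseline window [{lo}, {hi}) ms contains no samples")
    out = epochs.copy()
    out.data -= out.data[:, mask, :].mean(axis=1, keepdims=True)
    return out


def reject_artifacts(epochs: EpochArray, trials: pd.DataFrame,
                     threshold_uv: float = 100.0,
                     exclude_channels: tuple[str, ...] = ("M1", "M2"),
                     ) -> pd.DataFrame:
    """Flag trials where any scalp channel exceeds ``threshold_uv`` in magnitude.

    Returns a copy of the trial table with the ``artifact`` column set.
    Mastoid channels are not scalp sites and are skipped when present.
    """
    if threshold_uv <= 0:
        raise ParameterError("threshold must be positive")
    if len(trials) != epochs.n_trials:
        raise FormatError("trial table does not match the epoch count")
    keep = [i for i, ch in enumerate(epochs.channels) if ch not in exclude_channels]
    peak = np.abs(epochs.data[keep]).max(axis=(0, 1))
    out = trials.sort_values("trial_index").reset_index(drop=True).copy()
    out["artifact"] = peak > threshold_uv
    return out


def preprocess_epochs(epochs: EpochArray, trials: pd.DataFrame,
                      config: AnalysisConfig) -> tuple[EpochArray, pd.DataFrame]:
    """Full conditioning chain for one participant."""
    e = bandpass_filter(epochs, *config.bandpass)
    e = rereference_average(e)
    e = baseline_correct(e, config.baseline_window)
    t = reject_artifacts(e, trials, config.artifact_threshold_uv)
    return e, t


def _clean_cell_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Artifact-free trial counts per participant x dimension x item type."""
    clean = trials[~trials["artifact"]]
    counts = (clean.groupby(["participant_id", "dimension", "item_type"])
              .size().unstack(["dimension", "item_type"], fill_value=0))
    full = pd.MultiIndex.from_product([DIMENSIONS, ITEM_TYPES])
    return counts.reindex(columns=full, fill_value=0)


@dataclass
class ExclusionResult:
    retained: dict[str, list[str]]   # stage -> ids retained after that stage
    log: pd.DataFrame                # participant, stage, rule, n_before, n_after


def apply_exclusions(participants: pd.DataFrame, trials: pd.DataFrame,
                     config: AnalysisConfig) -> ExclusionResult:
    """Stage-wise participant exclusion with a reconciling log.

    vote_filter
        only mainstream and populist voters enter any analysis;
    erp_min_trials
        a participant needs at least ``min_trials_erp`` artifact-free epochs
        in *every* dimension x item-type cell to enter ERP averaging;
    mvpa_min_trials
        the decoding analyses require ``min_trials_mvpa`` per cell (applied
        to the vote-filtered sample, independently of the ERP rule);
    behav_missing
        participants without any usable agreement response are dropped from
        the self-report analyses.
    """
    check_participant_table(participants)
    check_trial_table(trials)
    unknown = set(participants["vote"]) - {"mainstream", "populist",
                                           "other_party", "nonvoter", "blank"}
    if unknown:
        raise FormatError(f"unknown vote code(s): {sorted(unknown)}")

    log_rows = []
    all_ids = list(participants["participant_id"])

    votes = participants.set_index("participant_id")["vote"]
    vote_keep = [i for i in all_ids if votes[i] in ANALYSIS_VOTES]
    for pid in all_ids:
        if pid not in vote_keep:
            log_rows.append((pid, "vote_filter",
                             f"vote={votes[pid]} not mainstream/populist",
                             len(all_ids), len(vote_keep)))

    counts = _clean_cell_counts(trials)

    def deficient(pid: str, minimum: int) -> bool:
        if pid not in counts.index:
            return True
        return int(counts.loc[pid].min()) < minimum

    erp_keep = [i for i in vote_keep if not deficient(i, config.min_trials_erp)]
    for pid in vote_keep:
        if pid not in erp_keep:
            log_rows.append((pid, "erp_min_trials",
                             f"<{config.min_trials_erp} artifact-free epochs in a condition",
                             len(vote_keep), len(erp_keep)))

    mvpa_keep = [i for i in vote_keep if not deficient(i, config.min_trials_mvpa)]
    for pid in vote_keep:
        if pid not in mvpa_keep:
            log_rows.append((pid, "mvpa_min_trials",
                             f"<{config.min_trials_mvpa} trials in a dimension x item-type cell",
                             len(vote_keep), len(mvpa_keep)))

    answered = trials[trials["agreement"].isin(["agree", "disagree"])]
    have_resp = set(answered["participant_id"])
    behav_keep = [i for i in vote_keep if i in have_resp]
    for pid in vote_keep:
        if pid not in behav_keep:
            log_rows.append((pid, "behav_missing",
                             "no usable agreement responses",
                             len(vote_keep), len(behav_keep)))

    log = pd.DataFrame(log_rows, columns=["participant_id", "stage", "rule",
                                          "n_before", "n_after"])
    return ExclusionResult(
        retained={"vote_filter": vote_keep, "erp_min_trials": erp_keep,
                  "mvpa_min_trials": mvpa_keep, "behav_missing": behav_keep},
        log=log)
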