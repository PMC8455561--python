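"""Core in-memory containers: epoched EEG and the tabular metadata.

The epoch container is a thin, validated wrapper around a channels x times x
trials voltage array. Tabular data (trials, participants, IAT latencies)
are plain pandas DataFrames with a required-column contract enforced by the
``check_*`` validators; this keeps them directly usable with pandas/statsmodels
idioms while still failing loudly on malformed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ParameterError

DIMENSIONS = ("anti_establishment", "economy", "culture")
ITEM_TYPES = ("populist", "non_populist")
VOTES = ("mainstream", "populist", "other_party", "nonvoter", "blank")
ANALYSIS_VOTES = ("mainstream", "populist")

TRIAL_COLUMNS = ("participant_id", "trial_index", "dimension", "item_type",
                 "agreement", "rt", "artifact")
PARTICIPANT_COLUMNS = ("participant_id", "vote", "age", "gender",
                       "left_right", "interest_politics")
IAT_COLUMNS = ("participant_id", "block", "trial_index", "latency")


@dataclass
class EpochArray:
    """Epoched voltages for one participant.

    data
        microvolts, shape ``(n_channels, n_times, n_trials)``.
    times
        milliseconds relative to critical-word onset, strictly increasing
        and uniformly spaced at ``1000 / sfreq``.
    channels
        ordered channel labels, shared across participants in a dataset.
    """

    data: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    sfreq: float
    participant_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.channels = tuple(str(c) for c in self.channels)
        if self.data.ndim != 3:
            raise FormatError("epoch data must be 3-D (channels, times, trials)")
        if self.data.shape[0] != len(self.channels):
            raise AlignmentError(
                f"{self.data.shape[0]} data channels vs {len(self.channels)} labels")
        if self.data.shape[1] != self.times.size:
            raise AlignmentError(
                f"{self.data.shape[1]} samples vs {self.times.size} time points")
        if self.sfreq <= 0:
            raise ParameterError("sfreq must be positive")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise FormatError("times must be strictly increasing")
            if not np.allclose(dt, 1000.0 / self.sfreq, rtol=1e-6, atol=1e-6):
                raise FormatError("times must be uniformly spaced at 1000/sfreq ms")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def copy(self) -> "EpochArray":
        return EpochArray(self.data.copy(), self.times.copy(), self.channels,
                          self.sfreq, self.participant_id)


def make_times(span_ms: tuple[float, float], sfreq: float) -> np.ndarray:
    """Uniform time axis over the half-open span ``[start, stop)`` ms."""
    start, stop = span_ms
    if stop <= start or sfreq <= 0:
        raise ParameterError("invalid epoch span or sampling rate")
    step = 1000.0 / sfreq
    n = int(np.floor((stop - start) / step + 1e-9))
    return start + step * np.arange(n)


# 61-channel analysis montage.  The 12 posterior electrodes used for N400
# measurement come first so that reduced montages (small n_channels in
# simulations) still resolve them by name; the remainder are standard
# 10-10-style labels.
_FULL_MONTAGE = (
    "CP1", "CP2", "CP3", "CP4", "P1", "P2", "P3", "P4", "Pz", "PO3", "PO4", "POz",
    "Oz", "O1", "O2", "PO7", "PO8", "P5", "P6", "P7", "P8",
    "CP5", "CP6", "TP7", "TP8", "Cz", "C1", "C2", "C3", "C4", "C5", "C6",
    "T7", "T8", "FCz", "FC1", "FC2", "FC3", "FC4", "FC5", "FC6", "FT7", "FT8",
    "Fz", "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8",
    "AF3", "AF4", "AF7", "AF8", "Fp1", "Fpz", "Fp2", "M1", "M2",
)
assert len(_FULL_MONTAGE) == 61


def make_montage(n_channels: int = 61) -> tuple[str, ...]:
    """Ordered channel labels for a montage of ``n_channels`` electrodes.

    Up to 61 channels the labels are drawn from the standard set, posterior
    electrodes first; beyond 61 systematic ``EXT##`` labels are appended.
    """
    if n_channels < 1:
        raise ParameterError("n_channels must be >= 1")
    if n_channels <= len(_FULL_MONTAGE):
        return _FULL_MONTAGE[:n_channels]
    extra = tuple(f"EXT{i:02d}" for i in range(1, n_channels - len(_FULL_MONTAGE) + 1))
    return _FULL_MONTAGE + extra


def _check_columns(df: pd.DataFrame, required, name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{name} is missing column(s): {', '.join(missing)}")


def check_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table (one row per epoch/trial)."""
    _check_columns(df, TRIAL_COLUMNS, "trial table")
    bad_dim = set(df["dimension"]) - set(DIMENSIONS)
    if bad_dim:
        raise FormatError(f"unknown issue dimension(s): {sorted(bad_dim)}")
    bad_it = set(df["item_type"]) - set(ITEM_TYPES)
    if bad_it:
        raise FormatError(f"unknown item type(s): {sorted(bad_it)}")
    bad_ag = set(df["agreement"].dropna()) - {"agree", "disagree", "missing"}
    if bad_ag:
        raise FormatError(f"unknown agreement value(s): {sorted(bad_ag)}")
    rts = df["rt"].dropna()
    if (rts <= 0).any():
        raise FormatError("response times must be positive or missing")
    return df


def check_participant_table(df: pd.DataFrame) -> pd.DataFrame:
    _check_columns(df, PARTICIPANT_COLUMNS, "participant table")
    if df["participant_id"].duplicated().any():
        raise FormatError("participant_id values must be unique")
    bad = set(df["vote"]) - set(VOTES)
    if bad:
        raise FormatError(f"unknown vote code(s): {sorted(bad)}")
    return df


def check_iat_table(df: pd.DataFrame) -> pd.DataFrame:
    _check_columns(df, IAT_COLUMNS, "IAT table")
    if not df["block"].isin(range(1, 8)).all():
        raise FormatError("IAT blocks must be in 1..7")
    if (df["latency"] <= 0).any():
        raise FormatError("IAT latencies must be positive")
    return df
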