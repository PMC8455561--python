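"""On-disk formats.

An epoch container is a trio of files sharing a stem:

``<stem>.npy``
    the voltage array, shape (n_channels, n_times, n_trials), float64 microvolts;
``<stem>.json``
    sidecar metadata: channels, times (ms), sfreq, participant_id;
``<stem>.trials.tsv``
    the trial table, rows aligned 1:1 with the trial axis.

A *dataset directory* holds ``participants.tsv``, optionally ``iat.tsv``,
and one epoch container per participant under ``epochs/``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (TRIAL_COLUMNS, EpochArray, check_iat_table,
                         check_participant_table, check_trial_table)
from .errors import AlignmentError, FormatError

_SIDECAR_KEYS = ("channels", "times", "sfreq", "participant_id")


def write_epochs(epochs: EpochArray, trials: pd.DataFrame, stem) -> Path:
    """Write one epoch container; returns the sidecar path stem."""
    stem = Path(stem)
    check_trial_table(trials)
    if len(trials) != epochs.n_trials:
        raise AlignmentError(
            f"{epochs.n_trials} epochs but {len(trials)} trial rows")
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(stem.with_suffix(".npy"), epochs.data)
    sidecar = {
        "channels": list(epochs.channels),
        "times": epochs.times.tolist(),
        "sfreq": epochs.sfreq,
        "participant_id": epochs.participant_id,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    trials.to_csv(stem.with_suffix(".trials.tsv"), sep="\t", index=False)
    return stem


def read_epochs(stem) -> tuple[EpochArray, pd.DataFrame]:
    """Read one epoch container written by :func:`write_epochs`."""
    stem = Path(stem)
    try:
        sidecar = json.loads(stem.with_suffix(".json").read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed sidecar {stem}.json: {exc}") from exc
    missing = [k for k in _SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise FormatError(
            f"sidecar {stem}.json is missing field(s): {', '.join(missing)}")
    data = np.load(stem.with_suffix(".npy"))
    epochs = EpochArray(data, np.asarray(sidecar["times"]),
                        tuple(sidecar["channels"]), float(sidecar["sfreq"]),
                        str(sidecar["participant_id"]))
    trials = check_trial_table(pd.read_csv(stem.with_suffix(".trials.tsv"), sep="\t"))
    if len(trials) != epochs.n_trials:
        raise AlignmentError(
            f"{stem}: {epochs.n_trials} epochs but {len(trials)} trial rows")
    return epochs, trials


def read_eeglab_epochs(path, participant_id: str | None = None
                       ) -> EpochArray:
    """Best-effort import of an EEGLAB-style epoched ``.set`` file.

    Reads MATLAB-format files whose top-level struct carries ``data``
    (channels x times x trials), ``times`` (ms), ``srate`` and a
    ``chanlocs`` label list.  Provided as a convenience for external
    deposits; not validated against any particular dataset.
    """
    from scipy.io import loadmat

    path = Path(path)
    mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    eeg = mat.get("EEG", mat)
    get = (lambda k: getattr(eeg, k, None)) if not isinstance(eeg, dict) \
        else eeg.get
    data, times, srate = get("data"), get("times"), get("srate")
    if data is None or times is None or srate is None:
        raise FormatError(f"{path} lacks data/times/srate fields")
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data[:, :, None]
    chanlocs = get("chanlocs")
    if chanlocs is not None:
        labels = tuple(str(getattr(c, "labels", c)) for c in np.atleast_1d(chanlocs))
    else:
        labels = tuple(f"CH{i + 1:02d}" for i in range(data.shape[0]))
    return EpochArray(data, np.asarray(times, dtype=float), labels,
                      float(srate), participant_id or path.stem)


def write_dataset(dataset, root) -> Path:
    """Write a full dataset (epochs per participant + tables) to ``root``."""
    root = Path(root)
    (root / "epochs").mkdir(parents=True, exist_ok=True)
    check_participant_table(dataset.participants).to_csv(
        root / "participants.tsv", sep="\t", index=False)
    if dataset.iat is not None:
        check_iat_table(dataset.iat).to_csv(root / "iat.tsv", sep="\t", index=False)
    for pid, epochs in dataset.epochs.items():
        trials = dataset.trials[dataset.trials["participant_id"] == pid]
        trials = trials.sort_values("trial_index").reset_index(drop=True)
        write_epochs(epochs, trials, root / "epochs" / pid)
    return root


def read_dataset(root):
    """Read a dataset directory; returns a :class:`~neurovote.simulate.Dataset`."""
    from .simulate import Dataset  # local import to avoid a cycle

    root = Path(root)
    pfile = root / "participants.tsv"
    if not pfile.exists():
        raise FormatError(f"{root} has no participants.tsv")
    participants = check_participant_table(pd.read_csv(pfile, sep="\t"))
    iat = None
    if (root / "iat.tsv").exists():
        iat = check_iat_table(pd.read_csv(root / "iat.tsv", sep="\t"))
    epochs: dict[str, EpochArray] = {}
    frames = []
    for sidecar in sorted((root / "epochs").glob("*.json")):
        e, t = read_epochs(sidecar.with_suffix(""))
        epochs[e.participant_id] = e
        frames.append(t)
    trials = (pd.concat(frames, ignore_index=True)
              if frames else pd.DataFrame(columns=list(TRIAL_COLUMNS)))
    return Dataset(participants=participants, trials=trials, epochs=epochs, iat=iat)
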