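import numpy as np
import pandas as pd
import pytest

from neurovote import AnalysisConfig, EpochArray, SimulationSpec, make_montage, make_times
from neurovote.simulate import simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_config():
    """Desk-scale analysis configuration (fast classifier, few repeats)."""
    return AnalysisConfig(seed=7, cv_repeats=2, chance_shuffles=1,
                          n_permutations=300, svm_backend="liblinear")


@pytest.fixture
def small_epochs(rng):
    """A small random epoch array with a valid montage and time axis."""
    channels = make_montage(16)
    times = make_times((-100.0, 1200.0), 128.0)
    data = rng.normal(0.0, 5.0, size=(16, times.size, 12))
    return EpochArray(data, times, channels, 128.0, "P001")


@pytest.fixture
def small_trials(small_epochs):
    n = small_epochs.n_trials
    dims = ["anti_establishment", "economy", "culture"] * (n // 3)
    items = ["populist", "non_populist"] * (n // 2)
    return pd.DataFrame({
        "participant_id": ["P001"] * n,
        "trial_index": range(n),
        "dimension": dims[:n],
        "item_type": items[:n],
        "agreement": ["agree"] * n,
        "rt": [800.0] * n,
        "artifact": [False] * n,
    })


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced-scale full dataset shared across tests (8 + 6 voters)."""
    spec = SimulationSpec(seed=42, n_channels=16, sfreq=128.0,
                          n_mainstream=8, n_populist=6)
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def roster_dataset():
    """The full 82-participant roster at reduced EEG scale."""
    spec = SimulationSpec.study_roster(seed=99, n_channels=16, sfreq=128.0)
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def roster_flagged(roster_dataset):
    """Roster trials after the conditioning chain (artifact flags set)."""
    from neurovote.preprocess import preprocess_epochs

    cfg = AnalysisConfig()
    frames = []
    for pid, e in roster_dataset.epochs.items():
        t = roster_dataset.trials[roster_dataset.trials["participant_id"] == pid]
        _, tt = preprocess_epochs(e, t, cfg)
        frames.append(tt)
    return pd.concat(frames, ignore_index=True)
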