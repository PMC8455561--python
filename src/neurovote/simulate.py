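"""Synthetic pre-electoral EEG/behavioral datasets.

The generator emulates the statistical structure the analysis chain assumes:

* a survey of 126 ten-word items — 3 issue dimensions (anti-establishment,
  economy, culture) x 2 item types (populist, non-populist) x 21 items —
  answered by future voters of mainstream and populist parties;
* 61-channel epochs spanning -100..1200 ms around the critical word, built
  from 1/f-shaped plus white Gaussian noise, with a *congruency* effect — an
  extra posterior negativity for items that contradict the participant's
  political group — injected for economy items in the N400 latency range
  (Gaussian kernel centred at 450 ms) and for culture items late in the
  epoch (centred at 1150 ms).  Anti-establishment items never carry an
  effect;
* agreement responses drawn through a logistic link on a per-participant
  latent populism score whose group separation exists for economy and
  culture but not for anti-establishment; response times are lognormal and
  group-independent;
* a 7-block IAT whose compatibility shift (blocks 6,7 vs 3,4) is drawn
  independently of voting group, so implicit-preference scores carry no
  group difference.

Defaults mirror the study roster: 40 mainstream + 29 populist voters in the
analysed sample; :meth:`SimulationSpec.study_roster` adds the 13 excluded
participants (9 other-party, 3 non-voters, 1 blank ballot), two participants
with unusable agreement responses and two with too few artifact-free epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (DIMENSIONS, ITEM_TYPES, EpochArray, make_montage,
                         make_times)
from .errors import ParameterError

__all__ = ["SimulationSpec", "Dataset", "simulate_participants",
           "simulate_behavior", "simulate_eeg", "simulate_iat",
           "simulate_dataset", "simulate_null_timecourses", "is_incongruent"]

# Posterior spatial profile of the injected effects: a smooth falloff away
# from POz where the congruency effect is largest.
_SPATIAL_WEIGHT = {
    "POz": 1.0, "PO3": 0.85, "PO4": 0.85, "Pz": 0.80,
    "P1": 0.70, "P2": 0.70, "P3": 0.55, "P4": 0.55,
    "Oz": 0.60, "O1": 0.45, "O2": 0.45, "PO7": 0.45, "PO8": 0.45,
    "CP1": 0.45, "CP2": 0.45, "CP3": 0.30, "CP4": 0.30,
    "P5": 0.40, "P6": 0.40, "P7": 0.25, "P8": 0.25,
    "CP5": 0.20, "CP6": 0.20,
}


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study."""

    # cohort
    n_mainstream: int = 40
    n_populist: int = 29
    n_other_party: int = 0
    n_nonvoter: int = 0
    n_blank: int = 0

    # EEG geometry
    n_channels: int = 61
    sfreq: float = 256.0          # Hz; the amplifier rate (2048) is also valid
    epoch_span: tuple[float, float] = (-100.0, 1200.0)  # ms, half-open
    trials_per_cell: int = 21     # items per dimension x item-type cell

    # injected congruency effects (microvolts; negative = N400-like)
    effect_amplitude_n400: float = -2.0   # economy items, N400 range
    effect_center_n400: float = 450.0     # ms
    effect_width_n400: float = 40.0       # Gaussian SD, ms
    effect_amplitude_late: float = -1.5   # culture items, late range
    effect_center_late: float = 1150.0
    effect_width_late: float = 60.0
    subject_sd: float = 1.0               # between-subject SD of effect amplitude

    # background noise: the 1/f ("brain") component is spatially structured
    # — a per-subject mixture of a few pink sources, as volume conduction
    # produces — while the sensor floor is independent white noise
    pink_sd: float = 4.0    # 1/f-shaped component, per-sample SD
    white_sd: float = 2.0   # white sensor-noise component, per-sample SD
    n_noise_sources: int = 0  # pink spatial modes; 0 = n_channels // 4

    # behavior; the separation is calibrated by simulation so the realized
    # group effect on the economy self-report index is d ~ 1.55
    attitude_sep: float = 1.6   # latent group separation, economy & culture
    attitude_sd: float = 1.0    # between-subject latent SD
    anti_establishment_mean: float = 0.5  # shared latent mean, both groups
    rt_median_ms: float = 1100.0
    rt_sigma: float = 0.35      # lognormal shape

    # IAT
    iat_block_sizes: tuple[int, ...] = (20, 20, 20, 40, 20, 20, 40)
    iat_base_median_ms: float = 700.0
    iat_sigma: float = 0.30
    iat_shift_mu_ms: float = 60.0   # compatibility shift, blocks 6 & 7
    iat_shift_sd_ms: float = 110.0  # drawn independently of voting group
    iat_floor_ms: float = 320.0

    # degraded-data bookkeeping (study_roster turns these on)
    n_missing_sri: int = 0        # participants whose responses were lost
    n_deficient_eeg: int = 0      # participants with too few clean epochs
    deficient_clean_trials: int = 13
    artifact_spike_uv: float = 500.0

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mainstream, self.n_populist) < 1:
            raise ParameterError("need at least one participant per voting group")
        if self.sfreq <= 0:
            raise ParameterError("sfreq must be positive")
        for name in ("subject_sd", "pink_sd", "white_sd", "attitude_sd",
                     "rt_sigma", "iat_sigma", "iat_shift_sd_ms"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.trials_per_cell < 1 or self.n_channels < 1:
            raise ParameterError("trials_per_cell and n_channels must be >= 1")
        if len(self.iat_block_sizes) != 7:
            raise ParameterError("iat_block_sizes must list 7 blocks")

    @classmethod
    def study_roster(cls, seed: int = 0, **overrides) -> "SimulationSpec":
        """The full 82-participant roster with the study's exclusions built in."""
        base = dict(n_mainstream=40, n_populist=29, n_other_party=9,
                    n_nonvoter=3, n_blank=1, n_missing_sri=2,
                    n_deficient_eeg=2, seed=seed)
        base.update(overrides)
        return cls(**base)

    def replace(self, **kwargs) -> "SimulationSpec":
        return replace(self, **kwargs)


@dataclass
class Dataset:
    """An in-memory dataset: tables plus per-participant epochs."""

    participants: pd.DataFrame
    trials: pd.DataFrame
    epochs: dict[str, EpochArray] = field(default_factory=dict)
    iat: pd.DataFrame | None = None


def is_incongruent(vote: str, item_type: str) -> bool:
    """A trial is incongruent when the item contradicts the voter's group."""
    return (vote == "mainstream" and item_type == "populist") or \
           (vote == "populist" and item_type == "non_populist")


def _participant_ids(spec: SimulationSpec) -> tuple[list[str], list[str]]:
    votes = (["mainstream"] * spec.n_mainstream + ["populist"] * spec.n_populist
             + ["other_party"] * spec.n_other_party + ["nonvoter"] * spec.n_nonvoter
             + ["blank"] * spec.n_blank)
    ids = [f"P{i + 1:03d}" for i in range(len(votes))]
    return ids, votes


def _special_ids(spec: SimulationSpec) -> tuple[list[str], list[str]]:
    """Deterministic choice of degraded participants.

    Missing self-reports hit the first mainstream voters; deficient EEG hits
    the last voters of each group (one per group when two are requested),
    so the two kinds of loss never overlap.
    """
    ids, votes = _participant_ids(spec)
    mains = [i for i, v in zip(ids, votes) if v == "mainstream"]
    pops = [i for i, v in zip(ids, votes) if v == "populist"]
    missing = mains[:spec.n_missing_sri]
    deficient: list[str] = []
    pools = [mains[::-1], pops[::-1]]
    k = 0
    while len(deficient) < spec.n_deficient_eeg:
        pool = pools[k % 2]
        cand = next(p for p in pool if p not in missing and p not in deficient)
        deficient.append(cand)
        k += 1
    return missing, deficient


def simulate_participants(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    ids, votes = _participant_ids(spec)
    n = len(ids)
    age = np.clip(np.round(rng.normal(24, 5, n)), 18, 55).astype(int)
    gender = np.where(rng.random(n) < 0.55, "female", "male")
    # left-right self-placement (1..10) leans right for populist voters;
    # interest in politics (1..5) is group-independent.
    lr_mean = np.where(np.asarray(votes) == "populist", 6.5, 4.5)
    left_right = np.clip(np.round(rng.normal(lr_mean, 1.8)), 1, 10).astype(int)
    interest = np.clip(np.round(rng.normal(3.3, 1.0, n)), 1, 5).astype(int)
    return pd.DataFrame({
        "participant_id": ids, "vote": votes, "age": age, "gender": gender,
        "left_right": left_right, "interest_politics": interest,
    })


def simulate_behavior(spec: SimulationSpec, rng: np.random.Generator,
                      participants: pd.DataFrame) -> pd.DataFrame:
    """Trial table with agreement and RT columns (no artifact flags yet)."""
    missing_ids, _ = _special_ids(spec)
    rows = []
    for _, p in participants.iterrows():
        pid, vote = p["participant_id"], p["vote"]
        group_sign = {"mainstream": -1.0, "populist": +1.0}.get(vote, 0.0)
        latent = {}
        for dim in DIMENSIONS:
            if dim == "anti_establishment":
                mu = spec.anti_establishment_mean
            else:
                mu = group_sign * spec.attitude_sep / 2.0
            latent[dim] = mu + rng.normal(0.0, spec.attitude_sd)
        cells = [(dim, it, k) for dim in DIMENSIONS for it in ITEM_TYPES
                 for k in range(spec.trials_per_cell)]
        order = rng.permutation(len(cells))
        for trial_index, ci in enumerate(order):
            dim, item_type, pair = cells[ci]
            x = latent[dim] if item_type == "populist" else -latent[dim]
            p_agree = 1.0 / (1.0 + math.exp(-x))
            agreement = "agree" if rng.random() < p_agree else "disagree"
            if pid in missing_ids:
                agreement = "missing"
            rt = float(rng.lognormal(math.log(spec.rt_median_ms), spec.rt_sigma))
            rows.append((pid, trial_index, dim, item_type, f"{dim}:{pair:02d}",
                         agreement, rt, False))
    return pd.DataFrame(rows, columns=["participant_id", "trial_index",
                                       "dimension", "item_type", "item_id",
                                       "agreement", "rt", "artifact"])


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                sfreq: float) -> np.ndarray:
    """1/f-amplitude noise along the last axis, unit variance."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec /= np.sqrt(freqs)
    out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std()
    return out / sd if sd > 0 else out


def _structured_noise(rng: np.random.Generator, n_channels: int,
                      n_trials: int, n_times: int, sfreq: float,
                      n_sources: int) -> np.ndarray:
    """Spatially correlated 1/f background: per-subject mixing of a small
    number of pink sources, unit variance per channel.

    Shape (n_channels, n_trials, n_times)."""
    k = max(1, n_sources)
    mixing = rng.standard_normal((n_channels, k))
    mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
    sources = _pink_noise(rng, (k, n_trials, n_times), sfreq)
    mixed = mixing @ sources.reshape(k, n_trials * n_times)
    return mixed.reshape(n_channels, n_trials, n_times)


def _effect_kernel(times: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times - center) / width) ** 2)


def simulate_eeg(spec: SimulationSpec, rng: np.random.Generator,
                 participants: pd.DataFrame,
                 trials: pd.DataFrame) -> dict[str, EpochArray]:
    """Per-participant epochs with congruency effects injected.

    Economy items carry the N400-range effect and culture items the late
    effect, on incongruent trials only; anti-establishment items never carry
    an effect.  Participants outside the two analysed voting groups have no
    defined congruency and receive background noise only.
    """
    channels = make_montage(spec.n_channels)
    times = make_times(spec.epoch_span, spec.sfreq)
    weights = np.array([_SPATIAL_WEIGHT.get(ch, 0.0) for ch in channels])
    kern_n400 = _effect_kernel(times, spec.effect_center_n400, spec.effect_width_n400)
    kern_late = _effect_kernel(times, spec.effect_center_late, spec.effect_width_late)
    _, deficient_ids = _special_ids(spec)

    votes = participants.set_index("participant_id")["vote"]
    by_pid = dict(tuple(trials.groupby("participant_id", sort=False)))
    out: dict[str, EpochArray] = {}
    for pid in participants["participant_id"]:
        vote = votes[pid]
        t = by_pid[pid].sort_values("trial_index")
        n_trials = len(t)
        k = spec.n_noise_sources or max(1, spec.n_channels // 4)
        data = spec.pink_sd * _structured_noise(
            rng, spec.n_channels, n_trials, times.size, spec.sfreq, k)
        data += spec.white_sd * rng.standard_normal(data.shape)
        data = np.ascontiguousarray(np.swapaxes(data, 1, 2))  # ch x time x trial

        amp_n400 = spec.effect_amplitude_n400 + spec.subject_sd * rng.standard_normal()
        amp_late = spec.effect_amplitude_late + spec.subject_sd * rng.standard_normal()
        if vote in ("mainstream", "populist"):
            incong = np.array([is_incongruent(vote, it) for it in t["item_type"]])
            for dim, kern, amp in (("economy", kern_n400, amp_n400),
                                   ("culture", kern_late, amp_late)):
                mask = incong & (t["dimension"] == dim).to_numpy()
                if mask.any():
                    data[:, :, mask] += amp * weights[:, None, None] * kern[None, :, None]

        if pid in deficient_ids:
            # contaminate enough economy/populist epochs that only
            # `deficient_clean_trials` clean ones remain in that cell
            cell = ((t["dimension"] == "economy")
                    & (t["item_type"] == "populist")).to_numpy()
            n_spike = max(0, int(cell.sum()) - spec.deficient_clean_trials)
            idx = np.flatnonzero(cell)[:n_spike]
            # a ~100 ms transient so the contamination survives band-pass
            # filtering and baseline correction downstream
            burst = _effect_kernel(times, 600.0, 50.0)
            data[0, :, idx] += spec.artifact_spike_uv * burst[None, :]

        out[pid] = EpochArray(data, times, channels, spec.sfreq, pid)
    return out


def simulate_iat(spec: SimulationSpec, rng: np.random.Generator,
                 participants: pd.DataFrame) -> pd.DataFrame:
    """Seven-block IAT latencies with a group-independent compatibility shift."""
    rows = []
    for pid in participants["participant_id"]:
        base_mu = math.log(spec.iat_base_median_ms) + rng.normal(0.0, 0.15)
        shift = rng.normal(spec.iat_shift_mu_ms, spec.iat_shift_sd_ms)
        for block, size in enumerate(spec.iat_block_sizes, start=1):
            lat = rng.lognormal(base_mu, spec.iat_sigma, size)
            if block in (6, 7):
                lat = lat + shift
            lat = np.maximum(lat, spec.iat_floor_ms)
            for k, v in enumerate(lat):
                rows.append((pid, block, k, float(v)))
    return pd.DataFrame(rows, columns=["participant_id", "block",
                                       "trial_index", "latency"])


def simulate_dataset(spec: SimulationSpec, include_eeg: bool = True,
                     include_iat: bool = True) -> Dataset:
    """Generate a complete dataset from one seeded stream."""
    rng = np.random.default_rng(spec.seed)
    participants = simulate_participants(spec, rng)
    trials = simulate_behavior(spec, rng, participants)
    epochs = (simulate_eeg(spec, rng, participants, trials)
              if include_eeg else {})
    iat = simulate_iat(spec, rng, participants) if include_iat else None
    return Dataset(participants=participants, trials=trials, epochs=epochs, iat=iat)


def simulate_null_timecourses(n_subjects: int, n_windows: int,
                              rng: np.random.Generator, acc_sd: float = 0.05,
                              dimension: str = "anti_establishment",
                              window_ms: float = 10.0) -> list:
    """Decoding timecourses with no information: real and empirical-chance
    accuracies drawn from the same distribution around 0.5.

    Used to calibrate the group-level cluster statistics without paying for
    classifier training on data known to carry no signal.
    """
    from .decoding import DecodingTimecourse

    starts = window_ms * np.arange(n_windows)
    out = []
    for i in range(n_subjects):
        out.append(DecodingTimecourse(
            participant_id=f"S{i + 1:03d}", dimension=dimension,
            window_starts=starts,
            real_accuracy=0.5 + acc_sd * rng.standard_normal(n_windows),
            chance_accuracy=0.5 + acc_sd * rng.standard_normal(n_windows)))
    return out
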