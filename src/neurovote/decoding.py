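"""Sliding-window multivariate decoding with cluster-mass permutation stats.

For each participant and issue dimension, a linear support vector machine
(C = 1) is trained to predict the item type (populist vs non-populist) from
the spatio-temporal voltage pattern inside consecutive, non-overlapping
10 ms windows.  Class imbalance is removed by undersampling the majority
class before each of ten repeats of a stratified ten-fold cross-validation;
the mean accuracy over the 10 x 10 analyses is the window's *real* accuracy.
The *empirical chance* accuracy is obtained by re-running the identical
procedure with the labels randomly shuffled.

Group-level inference compares real against chance accuracy per window with
a paired one-tailed t-test; runs of at least two consecutive windows below
the inclusion alpha form candidate clusters whose mass (summed t) is
compared against the maximum-cluster-mass distribution over sign-flip
permutations of the per-participant (real, chance) assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.svm import SVC, LinearSVC

from .config import AnalysisConfig
from .containers import EpochArray
from .errors import ParameterError

__all__ = ["DecodingTimecourse", "Cluster", "ClusterResult", "window_grid",
           "window_features", "balanced_cv_decode", "decode_timecourse",
           "cluster_permutation_test", "sanity_rerun", "cluster_overlap"]


@dataclass
class DecodingTimecourse:
    """Per participant x dimension information timecourse."""

    participant_id: str
    dimension: str
    window_starts: np.ndarray      # ms
    real_accuracy: np.ndarray      # proportion correct per window
    chance_accuracy: np.ndarray    # mean over shuffled-label reruns


@dataclass
class Cluster:
    start_idx: int
    end_idx: int          # inclusive
    start_ms: float
    stop_ms: float        # end of last window (half-open)
    mass: float           # summed t over the run
    p: float              # from the max-cluster-mass permutation distribution
    p_corrected: float    # after Bonferroni over dimensions


@dataclass
class ClusterResult:
    dimension: str
    window_starts: np.ndarray
    window_ms: float
    t: np.ndarray
    p_uncorrected: np.ndarray
    clusters: list[Cluster]
    n_subjects: int

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected < 0.05]


def window_grid(times: np.ndarray, window_ms: float,
                time_range: tuple[float, float] | None = None) -> list[tuple[float, float]]:
    """Non-overlapping half-open windows tiling the epoch (or a sub-range).

    The grid covers the *nominal* epoch span (last sample plus one sampling
    step), so a [-100, 1200) ms epoch yields ``floor(1300 / window_ms)``
    windows at any sampling rate.
    """
    dt = float(times[1] - times[0]) if times.size > 1 else 0.0
    t0 = times[0] if time_range is None else max(times[0], time_range[0])
    t1 = times[-1] + dt if time_range is None else min(times[-1] + dt,
                                                       time_range[1])
    n = int(np.floor((t1 - t0) / window_ms + 1e-9))
    return [(t0 + i * window_ms, t0 + (i + 1) * window_ms) for i in range(n)]


def window_features(epochs: EpochArray,
                    window: tuple[float, float]) -> np.ndarray:
    """Trials x features matrix for one half-open time window.

    Features are voltage samples from ``[start, stop)`` concatenated over
    channels.  The per-channel sample count is fixed at
    ``floor(window_ms * sfreq / 1000)`` — e.g. a 10 ms window at 2048 Hz
    over 61 channels gives 20 x 61 = 1220 features — independently of how
    the sampling grid happens to align with the window edges; surplus
    aligned samples are trimmed from the end.
    """
    lo, hi = window
    n_keep = int(np.floor((hi - lo) * epochs.sfreq / 1000.0 + 1e-9))
    mask = (epochs.times >= lo) & (epochs.times < hi)
    if n_keep < 1 or not mask.any():
        raise ParameterError(
            f"window [{lo}, {hi}) ms is empty at sfreq {epochs.sfreq} Hz")
    idx = np.flatnonzero(mask)[:n_keep]
    block = epochs.data[:, idx, :]           # ch x samples x trials
    n_feat = block.shape[0] * block.shape[1]
    return block.reshape(n_feat, block.shape[2]).T.copy()


def _make_classifier(config: AnalysisConfig):
    if config.svm_backend == "libsvm":
        return SVC(kernel="linear", C=config.svm_c)
    return LinearSVC(C=config.svm_c, dual="auto", max_iter=10000)


def _stratified_folds(y: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold assignment per trial, stratified by class; remainders are dealt
    round-robin across folds so fold sizes differ by at most one per class."""
    fold = np.empty(y.size, dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        assign = (np.arange(idx.size) + offset) % n_folds
        fold[idx] = assign
        offset += idx.size % n_folds
    return fold


def balanced_cv_decode(features: np.ndarray, labels: np.ndarray,
                       config: AnalysisConfig,
                       rng: np.random.Generator) -> float:
    """Mean cross-validated accuracy with class balancing.

    Per repeat: the majority class is undersampled to parity, trials are
    partitioned into ``cv_folds`` stratified folds, and a linear SVM (C = 1)
    is trained on all but one fold and tested on the held-out fold.  The
    returned accuracy is the mean over folds and repeats.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ParameterError("decoding requires exactly two classes")
    n_min = int(counts.min())
    if n_min < config.cv_folds:
        raise ParameterError(
            f"minority class has {n_min} trials < {config.cv_folds} folds")
    if config.feature_scaling:
        mu, sd = features.mean(axis=0), features.std(axis=0)
        features = (features - mu) / np.where(sd > 0, sd, 1.0)

    accs = []
    for _ in range(config.cv_repeats):
        keep = []
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            if idx.size > n_min:
                idx = rng.choice(idx, size=n_min, replace=False)
            keep.append(idx)
        keep = np.concatenate(keep)
        xb, yb = features[keep], labels[keep]
        fold = _stratified_folds(yb, config.cv_folds, rng)
        for k in range(config.cv_folds):
            test = fold == k
            clf = _make_classifier(config)
            clf.fit(xb[~test], yb[~test])
            accs.append(float(np.mean(clf.predict(xb[test]) == yb[test])))
    return float(np.mean(accs))


def decode_timecourse(epochs: EpochArray, trials: pd.DataFrame,
                      dimension: str, config: AnalysisConfig,
                      rng: np.random.Generator) -> DecodingTimecourse:
    """Real and empirical-chance accuracy per analysis window.

    Uses artifact-free trials of one issue dimension; the chance accuracy of
    a window is the mean over ``config.chance_shuffles`` reruns of the full
    balanced cross-validation with shuffled labels.
    """
    t = trials.sort_values("trial_index").reset_index(drop=True)
    if len(t) != epochs.n_trials:
        raise ParameterError("trial table does not align with epochs")
    sel = ((t["dimension"] == dimension) & (~t["artifact"])).to_numpy()
    labels = t.loc[sel, "item_type"].to_numpy()
    counts = pd.Series(labels).value_counts()
    if counts.min() < config.min_trials_mvpa or counts.size != 2:
        raise ParameterError(
            f"{epochs.participant_id}/{dimension}: fewer than "
            f"{config.min_trials_mvpa} trials in a class")

    windows = window_grid(epochs.times, config.mvpa_window_ms,
                          config.mvpa_time_range)
    if not windows:
        raise ParameterError(
            f"no {config.mvpa_window_ms:g} ms analysis windows fit the "
            "requested time range")
    real = np.empty(len(windows))
    chance = np.empty(len(windows))
    for i, win in enumerate(windows):
        feats = window_features(epochs, win)[sel]
        real[i] = balanced_cv_decode(feats, labels, config, rng)
        if config.chance_shuffles > 0:
            runs = [balanced_cv_decode(feats, rng.permutation(labels),
                                       config, rng)
                    for _ in range(config.chance_shuffles)]
            chance[i] = float(np.mean(runs))
        else:
            chance[i] = 0.5
    return DecodingTimecourse(epochs.participant_id, dimension,
                              np.array([w[0] for w in windows]), real, chance)


def _t_onesample(diffs: np.ndarray) -> np.ndarray:
    """One-sample t per column of a subjects x windows difference matrix."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd > 0, t, np.where(mean > 0, np.inf,
                                        np.where(mean < 0, -np.inf, 0.0)))


def _find_clusters(t: np.ndarray, t_crit: float,
                   min_len: int) -> list[tuple[int, int, float]]:
    """Runs of >= min_len consecutive windows with t > t_crit."""
    above = t > t_crit
    out = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                out.append((i, j, float(t[i:j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return out


def _max_masses(diffs: np.ndarray, signs: np.ndarray, t_crit: float,
                min_len: int) -> np.ndarray:
    """Max cluster mass per sign-flip permutation (rows of ``signs``).

    Under a sign flip the per-window second moment is unchanged, so the
    permuted t statistics reduce to matrix products — no classifier or
    cluster search re-run is required beyond the run-length scan.
    """
    n = diffs.shape[0]
    mean = signs @ diffs / n                       # n_perm x n_windows
    msq = (diffs ** 2).mean(axis=0)                # invariant to sign flips
    var = (msq - mean ** 2) * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmat = mean / np.sqrt(var / n)
    tmat = np.nan_to_num(tmat, nan=0.0, posinf=np.inf, neginf=-np.inf)
    out = np.zeros(signs.shape[0])
    for r in range(signs.shape[0]):
        clusters = _find_clusters(tmat[r], t_crit, min_len)
        if clusters:
            out[r] = max(c[2] for c in clusters)
    return out


def cluster_permutation_test(timecourses: list[DecodingTimecourse],
                             config: AnalysisConfig,
                             rng: np.random.Generator,
                             n_comparisons: int = 1) -> ClusterResult:
    """Group-level cluster-mass permutation test for one issue dimension.

    Per window, a paired one-tailed t-test of real > chance accuracy across
    participants; candidate clusters are runs of at least
    ``min_cluster_windows`` windows with p below ``cluster_alpha``.  The
    null distribution is the maximum cluster mass over permutations in which
    each participant's (real, chance) pair is independently swapped; the
    cluster p-value is the proportion of null masses at least as large
    (with the observed labelling included).  ``n_comparisons`` applies a
    Bonferroni factor across dimensions tested in the same family.
    """
    if len(timecourses) < 2:
        raise ParameterError("need at least two participants")
    starts = timecourses[0].window_starts
    dims = {tc.dimension for tc in timecourses}
    if len(dims) != 1:
        raise ParameterError("timecourses mix issue dimensions")
    for tc in timecourses:
        if tc.window_starts.shape != starts.shape or \
                not np.allclose(tc.window_starts, starts):
            raise ParameterError(
                f"window grid differs for participant {tc.participant_id}")
    diffs = np.array([tc.real_accuracy - tc.chance_accuracy
                      for tc in timecourses])
    n = diffs.shape[0]
    t_obs = _t_onesample(diffs)
    p_unc = sps.t.sf(np.nan_to_num(t_obs, posinf=1e12, neginf=-1e12), n - 1)
    t_crit = float(sps.t.ppf(1.0 - config.cluster_alpha, n - 1))
    found = _find_clusters(t_obs, t_crit, config.min_cluster_windows)

    clusters: list[Cluster] = []
    if found:
        signs = rng.choice([-1.0, 1.0], size=(config.n_permutations, n))
        null = _max_masses(diffs, signs, t_crit, config.min_cluster_windows)
        wms = float(starts[1] - starts[0]) if starts.size > 1 else config.mvpa_window_ms
        for (i, j, mass) in found:
            p = (1.0 + float(np.sum(null >= mass))) / (config.n_permutations + 1.0)
            clusters.append(Cluster(
                start_idx=i, end_idx=j, start_ms=float(starts[i]),
                stop_ms=float(starts[j] + wms), mass=mass, p=p,
                p_corrected=min(1.0, p * n_comparisons)))
    wms = float(starts[1] - starts[0]) if starts.size > 1 else config.mvpa_window_ms
    return ClusterResult(dimension=timecourses[0].dimension,
                         window_starts=starts, window_ms=wms, t=t_obs,
                         p_uncorrected=p_unc, clusters=clusters, n_subjects=n)


def cluster_overlap(a: Cluster, span: tuple[float, float]) -> float:
    """Fraction of ``span`` (ms) covered by cluster ``a``."""
    lo = max(a.start_ms, span[0])
    hi = min(a.stop_ms, span[1])
    width = span[1] - span[0]
    return max(0.0, hi - lo) / width if width > 0 else 0.0


def sanity_rerun(epochs_by_pid: dict[str, EpochArray], trials: pd.DataFrame,
                 dimension: str, config: AnalysisConfig,
                 rng: np.random.Generator,
                 window_ms: float = 20.0) -> dict:
    """Repeat the decoding chain at a doubled window size and report overlap.

    Returns the 10 ms-equivalent and the ``window_ms`` cluster results plus,
    per significant cluster of the base run, the best time-overlap fraction
    with a significant cluster of the rerun.
    """
    base_cfg = config
    alt_cfg = config.replace(mvpa_window_ms=window_ms)
    results = {}
    for label, cfg in (("base", base_cfg), ("alt", alt_cfg)):
        tcs = []
        for pid, e in epochs_by_pid.items():
            t = trials[trials["participant_id"] == pid]
            tcs.append(decode_timecourse(e, t, dimension, cfg, rng))
        results[label] = cluster_permutation_test(tcs, cfg, rng)
    overlaps = []
    for c in results["base"].significant_clusters:
        span = (c.start_ms, c.stop_ms)
        best = max((cluster_overlap(c2, span)
                    for c2 in results["alt"].significant_clusters), default=0.0)
        overlaps.append(best)
    return {"base": results["base"], "alt": results["alt"],
            "overlap_fractions": overlaps}
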