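"""Analysis configuration.

All defaults are the values used throughout the analysis chain: the N400
measurement window and posterior electrode set, the sliding-window decoding
parameters (10 ms non-overlapping windows, 10x10-fold cross-validation,
linear SVM with C = 1), the cluster-mass permutation settings (inclusion
alpha 0.05, 5000 permutation samples, minimum cluster extent of two
windows), the trial-count inclusion thresholds (14 artifact-free epochs per
condition for ERP averaging, 20 per cell for decoding), the 2700 ms
response-time trimming cutoff, and the IAT latency rules (delete > 10000 ms,
flag < 300 ms).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .errors import ParameterError

#: The 12 posterior electrodes over which N400 mean amplitudes are taken.
POSTERIOR_12 = (
    "CP1", "CP2", "CP3", "CP4",
    "P1", "P2", "P3", "P4", "Pz",
    "PO3", "PO4", "POz",
)


@dataclass
class AnalysisConfig:
    # N400 / ERP
    n400_window: tuple[float, float] = (300.0, 600.0)  # ms, half-open [start, stop)
    n400_channels: tuple[str, ...] = POSTERIOR_12
    baseline_window: tuple[float, float] = (-100.0, 0.0)  # ms
    bandpass: tuple[float, float] = (0.1, 30.0)  # Hz
    artifact_threshold_uv: float = 100.0  # |voltage| threshold for epoch rejection
    min_trials_erp: int = 14

    # decoding
    mvpa_window_ms: float = 10.0
    cv_folds: int = 10
    cv_repeats: int = 10
    svm_c: float = 1.0
    svm_backend: str = "libsvm"  # "libsvm" (SVC) or "liblinear" (LinearSVC)
    feature_scaling: bool = False
    chance_shuffles: int = 10  # shuffled-label reruns per window (mean = empirical chance)
    min_trials_mvpa: int = 20
    mvpa_time_range: tuple[float, float] | None = None  # restrict decoded windows; None = full epoch

    # cluster statistics
    n_permutations: int = 5000
    cluster_alpha: float = 0.05
    min_cluster_windows: int = 2

    # behavioral
    rt_cutoff_ms: float = 2700.0
    iat_delete_ms: float = 10000.0
    iat_min_ms: float = 300.0

    # voting models
    standardize_predictors: bool = True

    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        if self.cv_repeats < 1 or self.chance_shuffles < 0:
            raise ParameterError("cv_repeats must be >= 1 and chance_shuffles >= 0")
        if self.mvpa_window_ms <= 0:
            raise ParameterError("mvpa_window_ms must be positive")
        if not (0 < self.cluster_alpha < 1):
            raise ParameterError("cluster_alpha must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ParameterError("n_permutations must be >= 1")
        if self.svm_backend not in ("libsvm", "liblinear"):
            raise ParameterError(f"unknown svm_backend {self.svm_backend!r}")
        lo, hi = self.n400_window
        if not lo < hi:
            raise ParameterError("n400_window must satisfy start < stop")

    def replace(self, **kwargs) -> "AnalysisConfig":
        """Return a copy with selected fields overridden."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
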