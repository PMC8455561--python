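"""Self-report index, response-time conditioning, and IAT D-scoring.

The self-report index (SRI) adapts the Kelley index used in pre-electoral
surveys:  ``SRI = (% populist items agreed + % mainstream items disagreed)
- (% populist items disagreed + % mainstream items agreed)``, with the
percentages taken over the *answered* items of each item type, giving a
range of [-200, +200] (positive = more populist views).

The IAT D index follows the improved scoring algorithm: latencies above
10,000 ms are deleted, an *inclusive* standard deviation (sample SD of the
pooled latencies) is computed for combined blocks 3 & 6 and for blocks
4 & 7, and D is the equal-weight mean of the two block-pair mean
differences divided by their pooled SDs.  Positive D = faster responses in
the blocks pairing populist leaders with positive words.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ParameterError, ScoringError

__all__ = ["compute_sri", "trim_rts", "compute_d", "split_half_reliability"]

_TYPE_MAP = {"populist": "pop", "non_populist": "main"}


def compute_sri(trials: pd.DataFrame) -> pd.DataFrame:
    """SRI per participant x dimension.

    Returns columns ``participant_id, dimension, pop_agree, pop_disagree,
    main_agree, main_disagree, sri, missing``: the four component
    percentages (of answered items of that type), the index, and a flag set
    when a participant answered no item of some type for that dimension —
    such rows carry NaN rather than being silently dropped.
    """
    rows = []
    for (pid, dim), cell in trials.groupby(["participant_id", "dimension"],
                                           observed=True):
        comp = {}
        missing = False
        for item_type, tag in _TYPE_MAP.items():
            answered = cell[(cell["item_type"] == item_type)
                            & cell["agreement"].isin(["agree", "disagree"])]
            n = len(answered)
            if n == 0:
                comp[f"{tag}_agree"] = np.nan
                comp[f"{tag}_disagree"] = np.nan
                missing = True
            else:
                n_agree = int((answered["agreement"] == "agree").sum())
                comp[f"{tag}_agree"] = 100.0 * n_agree / n
                comp[f"{tag}_disagree"] = 100.0 * (n - n_agree) / n
        sri = (np.nan if missing else
               (comp["pop_agree"] + comp["main_disagree"])
               - (comp["pop_disagree"] + comp["main_agree"]))
        rows.append({"participant_id": pid, "dimension": dim, **comp,
                     "sri": sri, "missing": missing})
    return pd.DataFrame(rows)


def trim_rts(trials: pd.DataFrame,
             cutoff_ms: float = 2700.0) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Exclude slow trials from RT averaging.

    Returns ``(trimmed trials, per-condition mean RTs, derived cutoff)``
    where the condition is participant x dimension x item type and the
    derived cutoff is mean + 2 SD of the untrimmed RTs (reported alongside
    the fixed default for comparison).
    """
    if cutoff_ms <= 0:
        raise ParameterError("cutoff must be positive")
    rts = trials["rt"].dropna()
    derived = float(rts.mean() + 2.0 * rts.std(ddof=1)) if len(rts) > 1 else np.nan
    trimmed = trials[trials["rt"].notna() & (trials["rt"] <= cutoff_ms)]
    means = (trimmed.groupby(["participant_id", "dimension", "item_type"],
                             observed=True)["rt"]
             .mean().reset_index().rename(columns={"rt": "mean_rt"}))
    return trimmed, means, derived


def compute_d(iat: pd.DataFrame, delete_ms: float = 10000.0,
              min_ms: float = 300.0) -> pd.DataFrame:
    """IAT D score per participant.

    Columns: block means (``mean3, mean4, mean6, mean7``), the two pooled
    inclusive SDs (``sd_36, sd_47``), the two ratios (``d_first_pair`` from
    blocks 3/6, ``d_second_pair`` from blocks 4/7) and their equal-weight
    mean ``d``.  Latencies above ``delete_ms`` are deleted first; a warning
    is issued if any scored latency falls below ``min_ms``.
    """
    kept = iat[iat["latency"] <= delete_ms]
    if (kept["latency"] < min_ms).any():
        warnings.warn(f"IAT latencies below {min_ms:g} ms present after deletion",
                      stacklevel=2)
    rows = []
    for pid, sub in kept.groupby("participant_id"):
        blocks = {b: sub.loc[sub["block"] == b, "latency"].to_numpy()
                  for b in (3, 4, 6, 7)}
        for b, lat in blocks.items():
            if lat.size == 0:
                raise ScoringError(f"{pid}: scoring block {b} is empty")
        sd36 = float(np.std(np.concatenate([blocks[3], blocks[6]]), ddof=1))
        sd47 = float(np.std(np.concatenate([blocks[4], blocks[7]]), ddof=1))
        if sd36 == 0 or sd47 == 0:
            raise ScoringError(f"{pid}: zero inclusive SD in a block pair")
        d1 = (blocks[6].mean() - blocks[3].mean()) / sd36
        d2 = (blocks[7].mean() - blocks[4].mean()) / sd47
        rows.append({"participant_id": pid,
                     "mean3": blocks[3].mean(), "mean4": blocks[4].mean(),
                     "mean6": blocks[6].mean(), "mean7": blocks[7].mean(),
                     "sd_36": sd36, "sd_47": sd47,
                     "d_first_pair": float(d1), "d_second_pair": float(d2),
                     "d": float((d1 + d2) / 2.0)})
    return pd.DataFrame(rows)


def split_half_reliability(dscores: pd.DataFrame) -> tuple[float, float]:
    """Spearman-Brown adjusted split-half reliability of the D score.

    ``r`` is the Pearson correlation between the first-pair (blocks 3/6)
    and second-pair (blocks 4/7) D scores; the adjusted value is
    ``2 r / (1 + r)``.
    """
    sub = dscores[["d_first_pair", "d_second_pair"]].dropna()
    if len(sub) < 3:
        raise ParameterError("need at least 3 participants with both halves")
    r = float(np.corrcoef(sub["d_first_pair"], sub["d_second_pair"])[0, 1])
    return r, 2.0 * r / (1.0 + r)
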