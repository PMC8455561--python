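"""End-to-end analysis pipeline.

``run_pipeline`` chains preprocessing, the N400 ERP analysis, sliding-window
decoding, the behavioral indices and the voting-model comparison on an
in-memory or on-disk dataset, writing TSV tables plus a machine-readable
``results.json``.  Every participant exclusion is logged with its rule, and
two runs with the same configuration and seed produce identical output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decoding, erp, models, preprocess, stats
from .config import AnalysisConfig
from .containers import DIMENSIONS
from .errors import NeurovoteError, PipelineError
from .simulate import Dataset

__all__ = ["run_pipeline"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def _anova_records(table: pd.DataFrame) -> list[dict]:
    cols = ["effect", "F", "df1", "df2", "gg_eps", "p", "pes"]
    return _jsonable(table[cols])


def _cluster_records(result: decoding.ClusterResult) -> list[dict]:
    return [{"start_ms": c.start_ms, "stop_ms": c.stop_ms, "mass": c.mass,
             "p": c.p, "p_corrected": c.p_corrected}
            for c in result.clusters]


def run_pipeline(dataset: Dataset | str | Path, config: AnalysisConfig,
                 outdir: str | Path, run_decoding: bool = True) -> dict:
    """Execute preprocess -> erp -> decode -> behav -> predict and write a
    report bundle to ``outdir``.  Returns the results dictionary."""
    from .io import read_dataset

    if not isinstance(dataset, Dataset):
        dataset = read_dataset(dataset)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    results: dict = {"config": config.to_dict()}

    # ---- preprocessing + exclusions -------------------------------------
    stage = "preprocess"
    try:
        epochs, frames = {}, []
        for pid in sorted(dataset.epochs):
            try:
                e, t = preprocess.preprocess_epochs(
                    dataset.epochs[pid],
                    dataset.trials[dataset.trials["participant_id"] == pid],
                    config)
            except NeurovoteError as exc:
                raise PipelineError(stage, pid, str(exc)) from exc
            epochs[pid] = e
            frames.append(t)
        trials = (pd.concat(frames, ignore_index=True) if frames
                  else dataset.trials)
        excl = preprocess.apply_exclusions(dataset.participants, trials, config)
        excl.log.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
        results["exclusions"] = {
            "n_recruited": int(len(dataset.participants)),
            **{stage_: len(ids) for stage_, ids in excl.retained.items()},
        }
    except PipelineError:
        raise
    except NeurovoteError as exc:
        raise PipelineError(stage, None, str(exc)) from exc

    # ---- ERP / N400 ------------------------------------------------------
    stage = "erp"
    n400_diff = pd.Series(dtype=float)
    if epochs:
        try:
            erp_ids = [i for i in excl.retained["erp_min_trials"] if i in epochs]
            averages = erp.average_conditions(epochs, trials, erp_ids)
            n400 = erp.extract_n400(averages, config)
            n400.to_csv(outdir / "n400_amplitudes.tsv", sep="\t", index=False)
            suite = erp.n400_hypothesis_suite(n400, dataset.participants, config)
            n400_diff = erp.n400_differential(n400)
            results["n400"] = {
                "n_participants": len(erp_ids),
                "omnibus": _anova_records(suite["omnibus"]),
                "followup_dimension": {d: _anova_records(t) for d, t in
                                       suite["followup_dimension"].items()},
                "followup_group": {g: _anova_records(t) for g, t in
                                   suite["followup_group"].items()},
            }
        except NeurovoteError as exc:
            raise PipelineError(stage, None, str(exc)) from exc
    else:
        results["n400"] = None

    # ---- decoding --------------------------------------------------------
    stage = "decode"
    if run_decoding and epochs:
        try:
            mvpa_ids = [i for i in excl.retained["mvpa_min_trials"] if i in epochs]
            cluster_out = {}
            tc_rows = []
            for dim in DIMENSIONS:
                tcs = []
                for pid in mvpa_ids:
                    t = trials[trials["participant_id"] == pid]
                    try:
                        tcs.append(decoding.decode_timecourse(
                            epochs[pid], t, dim, config, rng))
                    except NeurovoteError as exc:
                        raise PipelineError(stage, pid, str(exc)) from exc
                for tc in tcs:
                    for w, r, c in zip(tc.window_starts, tc.real_accuracy,
                                       tc.chance_accuracy):
                        tc_rows.append((tc.participant_id, dim, w, r, c))
                res = decoding.cluster_permutation_test(
                    tcs, config, rng, n_comparisons=len(DIMENSIONS))
                cluster_out[dim] = res
            pd.DataFrame(tc_rows, columns=["participant_id", "dimension",
                                           "window_start_ms", "real_accuracy",
                                           "chance_accuracy"]).to_csv(
                outdir / "decoding_timecourses.tsv", sep="\t", index=False)
            results["decoding"] = {
                dim: {"n_subjects": res.n_subjects,
                      "clusters": _cluster_records(res)}
                for dim, res in cluster_out.items()}
        except PipelineError:
            raise
        except NeurovoteError as exc:
            raise PipelineError(stage, None, str(exc)) from exc
    else:
        results["decoding"] = None

    # ---- behavioral ------------------------------------------------------
    stage = "behav"
    try:
        behav_ids = excl.retained["behav_missing"]
        btrials = dataset.trials[dataset.trials["participant_id"].isin(
            excl.retained["vote_filter"])]
        sri = behavior.compute_sri(btrials)
        sri.to_csv(outdir / "sri.tsv", sep="\t", index=False)
        sri_groups = sri.merge(dataset.participants, on="participant_id")
        sri_tests = stats.independent_ttests_bonferroni(
            sri_groups.dropna(subset=["sri"]), "sri", "vote", "dimension")
        _, rt_means, derived_cutoff = behavior.trim_rts(btrials, config.rt_cutoff_ms)
        results["behavior"] = {
            "n_with_responses": len(behav_ids),
            "rt_cutoff_ms": config.rt_cutoff_ms,
            "rt_cutoff_derived_ms": derived_cutoff,
            "sri_group_means": _jsonable(
                sri_groups.groupby(["vote", "dimension"], observed=True)["sri"]
                .mean().unstack().round(3)),
            "sri_group_tests": _jsonable(sri_tests.round(5)),
        }
        if dataset.iat is not None:
            dscores = behavior.compute_d(dataset.iat, config.iat_delete_ms,
                                         config.iat_min_ms)
            dscores = dscores[dscores["participant_id"].isin(
                excl.retained["vote_filter"])]
            dscores.to_csv(outdir / "iat_d.tsv", sep="\t", index=False)
            r, r_sb = behavior.split_half_reliability(dscores)
            results["iat"] = {"mean_d": float(dscores["d"].mean()),
                              "split_half_r": r, "spearman_brown": r_sb}
        else:
            dscores = pd.DataFrame(columns=["participant_id", "d"])
            results["iat"] = None
    except NeurovoteError as exc:
        raise PipelineError(stage, None, str(exc)) from exc

    # ---- voting models ---------------------------------------------------
    stage = "predict"
    try:
        if len(n400_diff):
            frame, dropped = models.build_predictors(
                n400_diff, dscores, sri, dataset.participants,
                standardize=config.standardize_predictors)
            model_ids = ((1, 2, 3, 4, 5, 6) if "iat_d" in frame.columns
                         else (1, 3, 4, 5))
            suite = models.run_model_suite(frame, model_ids)
            models.table_one(suite).to_csv(outdir / "model_comparison.tsv",
                                           sep="\t")
            results["models"] = {
                "n_obs": suite[1][0].n_obs,
                "dropped": _jsonable(dropped),
                "metrics": {mid: {k: met[k] for k in
                                  ("mcfadden", "nagelkerke", "lambda_adj")}
                            for mid, (fit, met) in suite.items()},
            }
            fit4 = suite[4][0]
            w, p = models.wald_equality(fit4, "n400_economy", "sri_economy")
            results["models"]["wald_n400_vs_sri"] = {"W": w, "p": p}
        else:
            results["models"] = None
    except NeurovoteError as exc:
        raise PipelineError(stage, None, str(exc)) from exc

    (outdir / "results.json").write_text(
        json.dumps(_jsonable(results), indent=1, sort_keys=True))
    return results
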