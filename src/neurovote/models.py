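"""Logistic model comparison of implicit and explicit voting predictors.

Six nested/parallel logistic regressions of the vote (mainstream = 0,
populist = 1) are compared: (1) the N400 economy differential at POz,
(2) the IAT D score, (3) the economy SRI, (4) N400 + SRI, (5) a classic
socio-demographic model (age, age squared, gender, interest in politics,
left-right self-placement), (6) everything combined.  All models are fitted
on the identical complete-case rows, and compared on McFadden and
Nagelkerke pseudo-R-squared and on lambda, the proportional reduction in
classification error relative to always predicting the modal class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ParameterError, SeparationError

__all__ = ["ModelFit", "build_predictors", "fit_logistic", "model_metrics",
           "wald_equality", "run_model_suite", "MODEL_PREDICTORS", "table_one"]

MODEL_PREDICTORS: dict[int, tuple[str, ...]] = {
    1: ("n400_economy",),
    2: ("iat_d",),
    3: ("sri_economy",),
    4: ("n400_economy", "sri_economy"),
    5: ("age", "age_sq", "gender_male", "interest_politics", "left_right"),
    6: ("n400_economy", "iat_d", "sri_economy",
        "age", "age_sq", "gender_male", "interest_politics", "left_right"),
}

_CONTINUOUS = ("n400_economy", "iat_d", "sri_economy", "age", "age_sq",
               "interest_politics", "left_right")


@dataclass
class ModelFit:
    model_id: int
    predictors: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    loglik_model: float
    loglik_null: float
    n_obs: int
    fitted_prob: np.ndarray
    outcome: np.ndarray
    standardized: bool


def build_predictors(n400: pd.Series, dscores: pd.DataFrame,
                     sri: pd.DataFrame, participants: pd.DataFrame,
                     standardize: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join the per-participant predictors into a complete-case frame.

    Returns ``(frame, dropped)``; ``dropped`` logs each excluded participant
    with the reason.  Age squared is computed after centring age.  With
    ``standardize`` the continuous predictors are z-scored on the retained
    rows so that coefficients of different-unit predictors are comparable.
    """
    p = participants[participants["vote"].isin(["mainstream", "populist"])].copy()
    p = p.set_index("participant_id")
    frame = pd.DataFrame(index=p.index)
    frame["outcome"] = (p["vote"] == "populist").astype(int)
    frame["n400_economy"] = n400.reindex(p.index)
    dmap = dscores.set_index("participant_id")["d"] if len(dscores) else pd.Series(dtype=float)
    frame["iat_d"] = dmap.reindex(p.index)
    econ = sri[sri["dimension"] == "economy"].set_index("participant_id")["sri"]
    frame["sri_economy"] = econ.reindex(p.index)
    frame["age"] = p["age"].astype(float)
    frame["gender_male"] = (p["gender"] == "male").astype(float)
    frame["interest_politics"] = p["interest_politics"].astype(float)
    frame["left_right"] = p["left_right"].astype(float)

    required = ["n400_economy", "sri_economy", "age", "interest_politics",
                "left_right"]
    if len(dscores):  # the IAT is an optional instrument
        required.insert(1, "iat_d")
    reasons = []
    for pid, row in frame.iterrows():
        bad = [c for c in required if pd.isna(row[c])]
        if bad:
            stage = "behav_missing" if "sri_economy" in bad else "predictor_missing"
            reasons.append({"participant_id": pid, "stage": stage,
                            "rule": f"missing {', '.join(bad)}"})
    dropped = pd.DataFrame(reasons, columns=["participant_id", "stage", "rule"])
    frame = frame.dropna(subset=required + ["outcome"]).copy()
    if frame["iat_d"].isna().all():
        frame = frame.drop(columns="iat_d")

    age_c = frame["age"] - frame["age"].mean()
    frame["age_sq"] = age_c ** 2
    if standardize:
        for col in (c for c in _CONTINUOUS if c in frame.columns):
            sd = frame[col].std(ddof=1)
            if sd > 0:
                frame[col] = (frame[col] - frame[col].mean()) / sd
    frame = frame.sort_index()
    frame.attrs["standardized"] = bool(standardize)
    return frame, dropped


def fit_logistic(frame: pd.DataFrame, predictors: tuple[str, ...],
                 model_id: int = 0) -> ModelFit:
    """Maximum-likelihood logistic fit with an intercept-only null on the
    same rows; perfect separation aborts with a diagnostic error."""
    missing = [c for c in predictors if c not in frame.columns]
    if missing:
        raise ParameterError(f"frame lacks predictor column(s): {missing}")
    y = frame["outcome"].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ParameterError("outcome must contain both classes")
    x = sm.add_constant(frame[list(predictors)].astype(float), has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, x).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise SeparationError(
            f"model {model_id}: {exc}; consider penalized estimation "
            "(not applied automatically)") from exc
    prob = np.asarray(res.predict(x))
    if np.any(prob < 1e-10) or np.any(prob > 1 - 1e-10):
        # quasi-separation: fitted probabilities pinned at 0/1
        if res.llf > -1e-6 * len(y):
            raise SeparationError(
                f"model {model_id}: perfect separation detected; consider "
                "penalized estimation (not applied automatically)")
    null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
    return ModelFit(
        model_id=model_id, predictors=tuple(predictors),
        params=res.params, bse=res.bse,
        cov=pd.DataFrame(res.cov_params(), index=res.params.index,
                         columns=res.params.index),
        loglik_model=float(res.llf), loglik_null=float(null.llf),
        n_obs=int(len(y)), fitted_prob=prob, outcome=y.astype(int),
        standardized=bool(frame.attrs.get("standardized", False)))


def model_metrics(fit: ModelFit, threshold: float = 0.5) -> dict:
    """McFadden and Nagelkerke pseudo-R-squared and the lambda index.

    ``lambda = (C - M) / (n - M)`` where C is the count classified correctly
    at the given probability threshold and M the modal-class count; a model
    that always predicts the modal class scores exactly 0.
    """
    ll, ll0, n = fit.loglik_model, fit.loglik_null, fit.n_obs
    mcfadden = 1.0 - ll / ll0 if ll0 != 0 else np.nan
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
    nagelkerke = cox_snell / (1.0 - np.exp(2.0 * ll0 / n))
    pred = (fit.fitted_prob >= threshold).astype(int)
    correct = int(np.sum(pred == fit.outcome))
    modal = int(max(np.bincount(fit.outcome).max(), 1))
    lam = (correct - modal) / (n - modal) if n > modal else np.nan
    return {"mcfadden": float(mcfadden), "nagelkerke": float(nagelkerke),
            "lambda_adj": float(lam), "n_correct": correct, "n_modal": modal,
            "loglik_model": ll, "loglik_null": ll0, "n_obs": n}


def wald_equality(fit: ModelFit, coef_a: str, coef_b: str) -> tuple[float, float]:
    """Wald test of equality of two coefficients in one fitted model.

    ``W = (b_a - b_b)^2 / (var_a + var_b - 2 cov_ab)`` against chi2(1).
    """
    for c in (coef_a, coef_b):
        if c not in fit.params.index:
            raise ParameterError(f"coefficient {c!r} not in the model")
    diff = fit.params[coef_a] - fit.params[coef_b]
    var = (fit.cov.loc[coef_a, coef_a] + fit.cov.loc[coef_b, coef_b]
           - 2.0 * fit.cov.loc[coef_a, coef_b])
    if var <= 0:
        raise ParameterError("non-positive variance of the coefficient difference")
    w = float(diff ** 2 / var)
    return w, float(sps.chi2.sf(w, 1))


def run_model_suite(frame: pd.DataFrame,
                    models: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
                    ) -> dict[int, tuple[ModelFit, dict]]:
    """Fit the comparison models (all six by default) on identical rows."""
    needed = sorted({c for mid in models for c in MODEL_PREDICTORS[mid]})
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ParameterError(f"frame lacks predictor column(s): {missing}")
    out = {}
    for mid in models:
        preds = MODEL_PREDICTORS[mid]
        fit = fit_logistic(frame, preds, model_id=mid)
        out[mid] = (fit, model_metrics(fit))
    ns = {m[0].n_obs for m in out.values()}
    if len(ns) != 1:
        raise ParameterError("models were fitted on differing observation counts")
    return out


def table_one(suite: dict[int, tuple[ModelFit, dict]]) -> pd.DataFrame:
    """Comparison table: one column per model, rows = coefficients (SE) and
    fit metrics."""
    rows = sorted({c for fit, _ in suite.values() for c in fit.params.index
                   if c != "const"})
    table = {}
    for mid, (fit, met) in sorted(suite.items()):
        col = {}
        for r in rows:
            if r in fit.params.index:
                col[r] = f"{fit.params[r]:.3f} ({fit.bse[r]:.3f})"
        col["const"] = f"{fit.params['const']:.3f} ({fit.bse['const']:.3f})"
        col["observations"] = fit.n_obs
        col["mcfadden"] = round(met["mcfadden"], 3)
        col["nagelkerke"] = round(met["nagelkerke"], 3)
        col["lambda_adj"] = round(met["lambda_adj"], 3)
        table[f"model_{mid}"] = col
    return pd.DataFrame(table).reindex(rows + ["const", "observations",
                                               "mcfadden", "nagelkerke",
                                               "lambda_adj"])
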