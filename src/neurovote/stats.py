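"""Mixed-design ANOVA and small-sample test helpers.

The mixed ANOVA follows the classical univariate (split-plot) approach,
computed through orthonormal contrasts on the within-subject cells:

* each within-subject effect is represented by the Kronecker product of
  orthonormal Helmert contrasts (involved factors) and normalized mean
  vectors (uninvolved factors);
* contrast scores ``Z = W M`` are analysed with the between-subjects linear
  model (intercept + effect-coded group), giving Type-III sums of squares —
  with unequal group sizes the within effects test the unweighted mean of
  the group means;
* Greenhouse-Geisser epsilon is computed from the eigenvalues of the pooled
  within-group covariance of the contrast scores,
  ``eps = (sum lambda)^2 / (q * sum lambda^2)``, and Mauchly's test at
  alpha = 0.05 decides whether the corrected p-value is adopted;
* partial eta squared is ``SS_effect / (SS_effect + SS_error)`` within each
  error stratum.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

__all__ = ["mixed_anova", "gg_epsilon", "mauchly_test", "cohens_d",
           "independent_ttests_bonferroni"]


def _helmert(k: int) -> np.ndarray:
    """Orthonormal (k, k-1) contrast basis orthogonal to the constant."""
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def _sse(x: np.ndarray | None, z: np.ndarray) -> float:
    """Residual sum of squares of Z on design X (X=None: no regressors)."""
    if x is None or x.shape[1] == 0:
        return float((z ** 2).sum())
    beta, *_ = np.linalg.lstsq(x, z, rcond=None)
    resid = z - x @ beta
    return float((resid ** 2).sum())


def gg_epsilon(sigma: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a contrast-score covariance matrix."""
    q = sigma.shape[0]
    if q == 1:
        return 1.0
    lam = np.linalg.eigvalsh(sigma)
    lam = np.clip(lam, 0.0, None)
    denom = q * float((lam ** 2).sum())
    if denom <= 0:
        return 1.0
    eps = float(lam.sum()) ** 2 / denom
    return float(np.clip(eps, 1.0 / q, 1.0))


def mauchly_test(sigma: np.ndarray, n_error: int) -> tuple[float, float]:
    """Mauchly's sphericity test; returns (W, p).

    ``n_error`` is the error degrees of freedom used to estimate ``sigma``
    (number of subjects minus number of groups).  With one contrast column
    sphericity holds trivially and (1, 1) is returned.
    """
    q = sigma.shape[0]
    if q == 1 or n_error <= q:
        return 1.0, 1.0
    eig = np.linalg.eigvalsh(sigma)
    if np.any(eig <= 1e-14):
        return 0.0, 0.0
    w = float(np.exp(np.log(eig).sum() - q * np.log(eig.mean())))
    df = q * (q + 1) // 2 - 1
    mult = 1.0 - (2.0 * q ** 2 + q + 2.0) / (6.0 * q * n_error)
    chi2 = -n_error * mult * math.log(max(w, 1e-300))
    return w, float(sps.chi2.sf(chi2, df))


def _pivot_wide(data: pd.DataFrame, dv: str, subject: str,
                within: list[str]) -> tuple[pd.DataFrame, list[np.ndarray]]:
    levels = [list(pd.unique(data[f])) for f in within]
    wide = data.pivot_table(index=subject, columns=within, values=dv,
                            aggfunc="mean", observed=True)
    if len(within) == 1:
        full = pd.Index(levels[0], name=within[0])
    else:
        full = pd.MultiIndex.from_product(levels, names=within)
    wide = wide.reindex(columns=full)
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any(axis=0)][0]
        raise ParameterError(f"missing within-subject cell: {bad!r}")
    counts = data.groupby([subject] + within, observed=True).size()
    if (counts != 1).any():
        raise ParameterError("design must have exactly one observation per "
                             "subject x within-cell (aggregate first)")
    return wide, levels


def mixed_anova(data: pd.DataFrame, dv: str, subject: str,
                between: str | None, within: list[str],
                sphericity_alpha: float = 0.05) -> pd.DataFrame:
    """Mixed-design ANOVA table (one between factor, arbitrary crossed within).

    Returns one row per effect with columns ``effect, SS, SS_error, df1, df2,
    F, p_unc, gg_eps, p_gg, mauchly_W, mauchly_p, sphericity_violated, p,
    pes``.  ``p`` is the Greenhouse-Geisser-corrected value when Mauchly's
    test rejects at ``sphericity_alpha``, otherwise the uncorrected one.
    ``between=None`` analyses a single group (within effects only).
    """
    if not within:
        raise ParameterError("at least one within factor is required")
    wide, levels = _pivot_wide(data, dv, subject, within)
    n = len(wide)

    if between is None:
        groups = pd.Series(["_all"] * n, index=wide.index)
    else:
        gmap = data.groupby(subject, observed=True)[between].agg(pd.unique)
        if gmap.map(len).max() > 1:
            raise ParameterError("a subject appears in more than one group")
        groups = gmap.map(lambda v: v[0]).reindex(wide.index)
    glev = list(pd.unique(groups))
    g = len(glev)
    if between is not None and g < 2:
        raise ParameterError(f"between factor {between!r} needs >= 2 levels")
    if n - g < 1:
        raise ParameterError("not enough subjects for the error term")

    # effect-coded between design
    xg = np.zeros((n, g - 1))
    for j, lev in enumerate(glev[:-1]):
        xg[:, j] = np.where(groups == lev, 1.0, 0.0)
    xg[np.asarray(groups == glev[-1]), :] = -1.0
    ones = np.ones((n, 1))
    xfull = np.hstack([ones, xg])

    contrasts = [_helmert(len(lv)) for lv in levels]
    means = [np.full((len(lv), 1), 1.0 / math.sqrt(len(lv))) for lv in levels]
    w = wide.to_numpy()

    rows = []

    def add_row(effect, ss, ss_err, df1, df2, eps, mw, mp):
        f = (ss / df1) / (ss_err / df2) if ss_err > 0 else np.inf
        p_unc = float(sps.f.sf(f, df1, df2))
        p_gg = float(sps.f.sf(f, eps * df1, eps * df2))
        violated = (mp < sphericity_alpha) and eps < 1.0
        rows.append({
            "effect": effect, "SS": ss, "SS_error": ss_err,
            "df1": df1, "df2": df2, "F": f, "p_unc": p_unc,
            "gg_eps": eps, "p_gg": p_gg, "mauchly_W": mw, "mauchly_p": mp,
            "sphericity_violated": bool(violated),
            "p": p_gg if violated else p_unc,
            "pes": ss / (ss + ss_err) if (ss + ss_err) > 0 else np.nan,
        })

    # between-subjects effect (on the subject means over within cells)
    if between is not None:
        u_all = means[0]
        for m in means[1:]:
            u_all = np.kron(u_all, m)
        z = w @ u_all
        ss_b = _sse(ones, z) - _sse(xfull, z)
        ss_e = _sse(xfull, z)
        add_row(between, ss_b, ss_e, g - 1, n - g, 1.0, 1.0, 1.0)

    # within effects and their interactions with the between factor
    for size in range(1, len(within) + 1):
        for combo in itertools.combinations(range(len(within)), size):
            mats = [contrasts[i] if i in combo else means[i]
                    for i in range(len(within))]
            m = mats[0]
            for mat in mats[1:]:
                m = np.kron(m, mat)
            q = m.shape[1]
            z = w @ m
            ss_err = _sse(xfull, z)
            beta, *_ = np.linalg.lstsq(xfull, z, rcond=None)
            resid = z - xfull @ beta
            sigma = resid.T @ resid / (n - g)
            eps = gg_epsilon(sigma)
            mw, mp = mauchly_test(sigma, n - g)
            name = "*".join(within[i] for i in combo)

            ss_w = _sse(xg if g > 1 else None, z) - ss_err
            add_row(name, ss_w, ss_err, q, q * (n - g), eps, mw, mp)
            if between is not None:
                ss_int = _sse(ones, z) - ss_err
                add_row(f"{between}*{name}", ss_int, ss_err,
                        q * (g - 1), q * (n - g), eps, mw, mp)

    return pd.DataFrame(rows)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Independent-samples Cohen's d with pooled SD."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                   / (na + nb - 2))
    return float((a.mean() - b.mean()) / sp) if sp > 0 else np.nan


def independent_ttests_bonferroni(data: pd.DataFrame, dv: str, group: str,
                                  by: str) -> pd.DataFrame:
    """Independent-samples t-tests of ``dv`` between the two ``group`` levels,
    run separately per level of ``by``, Bonferroni-corrected across them."""
    out = []
    levels = list(pd.unique(data[by]))
    glev = list(pd.unique(data[group]))
    if len(glev) != 2:
        raise ParameterError("exactly two groups are required")
    for lev in levels:
        sub = data[data[by] == lev]
        a = sub.loc[sub[group] == glev[0], dv].dropna().to_numpy()
        b = sub.loc[sub[group] == glev[1], dv].dropna().to_numpy()
        t, p = sps.ttest_ind(a, b)
        out.append({by: lev, "t": float(t), "df": a.size + b.size - 2,
                    "p": float(p),
                    "p_bonf": float(min(1.0, p * len(levels))),
                    "cohen_d": cohens_d(a, b),
                    f"mean_{glev[0]}": a.mean(), f"mean_{glev[1]}": b.mean()})
    return pd.DataFrame(out)
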