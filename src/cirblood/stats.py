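"""Inferential kernels shared by all screens.

* Benjamini-Hochberg and Bonferroni multiplicity adjustment
* TOST equivalence testing with Welch one-sided t-tests
* rank-based ANOVA-type statistic (ATS) for one-group repeated measures,
  with the Box-type F approximation for its degrees of freedom
* rank-based Wald-type statistic (WTS) for factorial interaction effects
* linear mixed model Wald tests (random patient intercept, REML)

The two rank statistics operate on joint mid-ranks and are therefore
invariant under strictly monotone transforms of the data.  The WTS treats
observations as independent across subjects and timepoints (the
between-subject factorial convention); this limitation is deliberate and
recorded in screen output metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

log = logging.getLogger(__name__)


class DesignError(ValueError):
    """Invalid design for a statistical kernel."""


# ---------------------------------------------------------------------------
# multiplicity adjustment
# ---------------------------------------------------------------------------

def _check_pvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0,1]")
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = _check_pvalues(p)
    if p.size == 0:
        return p
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def bonferroni_adjust(p) -> np.ndarray:
    p = _check_pvalues(p)
    m = int(np.sum(~np.isnan(p)))
    return np.minimum(p * m, 1.0)


def screen_frame(gene_ids, estimates, raw_p, adjustment: str,
                 threshold: float) -> pd.DataFrame:
    """Assemble the per-gene screen output table.

    ``adjustment`` is ``BH``, ``Bonferroni`` or ``none``; ``significant``
    is defined as adjusted p strictly below ``threshold``.
    """
    raw_p = _check_pvalues(raw_p)
    if adjustment == "BH":
        adj = bh_adjust(raw_p)
    elif adjustment == "Bonferroni":
        adj = bonferroni_adjust(raw_p)
    elif adjustment == "none":
        adj = raw_p.copy()
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return pd.DataFrame({
        "gene_id": list(gene_ids),
        "estimate": np.asarray(estimates, dtype=float),
        "raw_p": raw_p,
        "adj_p": adj,
        "adjustment": adjustment,
        "significant": adj < threshold,
    })


# ---------------------------------------------------------------------------
# TOST equivalence
# ---------------------------------------------------------------------------

@dataclass
class TostResult:
    p: float
    equivalent: bool
    p_lower: float
    p_upper: float
    degenerate: bool = False


def tost_equivalence(a, b, margin: float, alpha: float = 0.05) -> TostResult:
    """Two one-sided Welch t-tests of equivalence within ``+/- margin``.

    p is the larger of the two one-sided p-values; equivalence is declared
    when p < alpha.  Zero-variance degeneracies are decided by the raw
    mean difference and flagged.
    """
    if margin <= 0:
        raise ValueError(f"equivalence margin must be positive, got {margin}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DesignError("each sample needs at least 2 observations")
    d = a.mean() - b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        inside = abs(d) < margin
        return TostResult(p=0.0 if inside else 1.0, equivalent=inside,
                          p_lower=np.nan, p_upper=np.nan, degenerate=True)
    se = np.sqrt(va / a.size + vb / b.size)
    df = (va / a.size + vb / b.size) ** 2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1))
    # H0: d <= -margin (reject for large t)   /   H0: d >= +margin
    t_lower = (d + margin) / se
    t_upper = (d - margin) / se
    p_lower = sps.t.sf(t_lower, df)
    p_upper = sps.t.cdf(t_upper, df)
    p = max(p_lower, p_upper)
    return TostResult(p=float(p), equivalent=bool(p < alpha),
                      p_lower=float(p_lower), p_upper=float(p_upper))


# ---------------------------------------------------------------------------
# rank-based ANOVA-type statistic (one within-subject factor)
# ---------------------------------------------------------------------------

@dataclass
class AtsResult:
    statistic: float
    df1: float
    df2: float
    p: float
    relative_effects: np.ndarray
    n_subjects: int


def ats_test(values, subjects, levels) -> AtsResult:
    """ANOVA-type statistic for a one-group repeated-measures design.

    ``values`` are scored by joint mid-ranks; subjects observed at fewer
    than two levels are dropped (they carry no within-subject contrast);
    remaining missing cells contribute through pairwise-complete
    covariance estimation.  The p-value uses the Box-type approximation
    F(f1, inf) — equivalently chi-square(f1)/f1 — with
    f1 = tr(TV)^2 / tr((TV)^2); the within-subject covariance enters
    through the subject-wise rank-vector covariance estimate.
    """
    values = np.asarray(values, dtype=float)
    subjects = np.asarray(subjects)
    levels = np.asarray(levels)
    lev_ids = np.unique(levels)
    a = lev_ids.size
    if a < 2:
        raise DesignError("need at least 2 factor levels")

    # drop subjects observed at < 2 levels
    keep_subj = []
    for s in np.unique(subjects):
        if np.unique(levels[subjects == s]).size >= 2:
            keep_subj.append(s)
    keep = np.isin(subjects, keep_subj)
    values, subjects, levels = values[keep], subjects[keep], levels[keep]
    subj_ids = np.unique(subjects)
    n = subj_ids.size
    if n < 3:
        raise DesignError(f"need at least 3 subjects with >=2 levels, got {n}")

    N = values.size
    ranks = sps.rankdata(values)
    li = np.searchsorted(lev_ids, levels)
    si = np.searchsorted(subj_ids, subjects)
    R = np.full((a, n), np.nan)
    R[li, si] = ranks

    n_i = np.sum(~np.isnan(R), axis=1)
    if np.any(n_i < 2):
        bad = lev_ids[n_i < 2]
        raise DesignError(f"level(s) {list(bad)} observed in < 2 subjects")

    Y = R / N
    p_hat = (np.nanmean(R, axis=1) - 0.5) / N

    # pairwise-complete covariance of subject vectors, scaled to Cov(p_hat)
    S = np.zeros((a, a))
    Vp = np.zeros((a, a))
    for i in range(a):
        for j in range(i, a):
            both = ~np.isnan(Y[i]) & ~np.isnan(Y[j])
            nij = int(both.sum())
            if nij >= 2:
                yi, yj = Y[i, both], Y[j, both]
                S[i, j] = S[j, i] = np.sum(
                    (yi - yi.mean()) * (yj - yj.mean())) / (nij - 1)
                Vp[i, j] = Vp[j, i] = S[i, j] * nij / (n_i[i] * n_i[j])

    T = np.eye(a) - np.ones((a, a)) / a
    num = float(p_hat @ T @ p_hat)
    TV = T @ Vp
    den = float(np.trace(TV))
    if den <= 0:
        # no estimable contrast variance: either no rank variation at all
        # (p = 1) or a perfectly consistent shift (maximal evidence)
        if num <= 1e-14:
            return AtsResult(0.0, np.nan, np.inf, 1.0, p_hat, n)
        return AtsResult(np.inf, np.nan, np.inf, 0.0, p_hat, n)
    stat = num / den
    tr2 = float(np.trace(TV @ TV))
    df1 = den ** 2 / tr2 if tr2 > 0 else np.nan
    if not np.isfinite(df1):
        return AtsResult(stat, df1, np.inf, 1.0, p_hat, n)
    p = float(sps.chi2.sf(stat * df1, df1))
    return AtsResult(float(stat), float(df1), np.inf, p, p_hat, n)


# ---------------------------------------------------------------------------
# rank-based Wald-type interaction statistic (two crossed factors)
# ---------------------------------------------------------------------------

@dataclass
class WtsResult:
    statistic: float
    df: int
    p: float
    relative_effects: np.ndarray   # a x b


def wts_rank_interaction(values, factor_a, factor_b) -> WtsResult:
    """Wald-type statistic for the A x B interaction on joint mid-ranks.

    Cell-wise relative effects are contrasted with the doubly-centering
    interaction matrix; the quadratic form uses a consistently estimated
    diagonal covariance (observations treated as independent), with a
    Moore-Penrose inverse and a chi-square reference on (a-1)(b-1) df.
    """
    values = np.asarray(values, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    a_ids, ai = np.unique(factor_a, return_inverse=True)
    b_ids, bi = np.unique(factor_b, return_inverse=True)
    a, b = a_ids.size, b_ids.size
    if a < 2 or b < 2:
        raise DesignError("both factors need at least 2 levels")
    N = values.size
    ranks = sps.rankdata(values)

    p_hat = np.zeros(a * b)
    var_p = np.zeros(a * b)
    for i in range(a):
        for j in range(b):
            cell = (ai == i) & (bi == j)
            nij = int(cell.sum())
            if nij == 0:
                raise DesignError(
                    f"empty cell A={a_ids[i]}, B={b_ids[j]}")
            r = ranks[cell]
            p_hat[i * b + j] = (r.mean() - 0.5) / N
            if nij >= 2:
                var_p[i * b + j] = r.var(ddof=1) / (N ** 2 * nij)

    Pa = np.eye(a) - np.ones((a, a)) / a
    Pb = np.eye(b) - np.ones((b, b)) / b
    C = np.kron(Pa, Pb)
    q = C @ p_hat
    M = C @ np.diag(var_p) @ C.T
    stat = float(q @ np.linalg.pinv(M, rcond=1e-12) @ q)
    df = (a - 1) * (b - 1)
    return WtsResult(stat, df, float(sps.chi2.sf(stat, df)),
                     p_hat.reshape(a, b))


# ---------------------------------------------------------------------------
# linear mixed model Wald tests
# ---------------------------------------------------------------------------

@dataclass
class MixedWaldResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    used_ols: bool


def mixed_model_wald(y, fixed: pd.DataFrame, groups) -> MixedWaldResult:
    """Random-intercept linear mixed model (REML) with Wald z tests.

    ``fixed`` holds the named covariate columns (an intercept is added).
    Falls back to OLS with a logged warning when the random-effect
    variance estimate collapses to zero or the fit fails.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if np.unique(groups).size < 2:
        raise DesignError("need at least 2 groups")
    X = pd.DataFrame({"intercept": np.ones(len(y))})
    for c in fixed.columns:
        X[c] = np.asarray(fixed[c], dtype=float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError(
            f"singular fixed-effect design (columns {list(X.columns)})")

    used_ols = False
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs"):
            try:
                res = MixedLM(y, X, groups=groups).fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                res = None
                continue
            if np.all(np.isfinite(res.bse.iloc[:X.shape[1]])):
                break
            res = None
    if res is not None and float(res.cov_re.iloc[0, 0]) <= 1e-10:
        res = None
        log.debug("random-effect variance ~0; falling back to OLS")
    if res is None:
        used_ols = True
        ols = sm.OLS(y, X).fit()
        return MixedWaldResult(params=ols.params, bse=ols.bse,
                               pvalues=ols.pvalues, used_ols=True)
    k = X.shape[1]
    return MixedWaldResult(params=res.params.iloc[:k], bse=res.bse.iloc[:k],
                           pvalues=res.pvalues.iloc[:k], used_ols=used_ols)
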