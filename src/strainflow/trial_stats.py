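"""Trial statistics: ANCOVA-adjusted growth comparison, non-inferiority
decisions, sample size, relative risk, exact r×c tests, biomarker
censoring rules, and Benjamini-Hochberg adjustment.

The primary-outcome machinery follows standard non-inferiority practice:
daily weight gain is compared between arms with an ANCOVA correcting for
baseline weight and sex; pairwise group differences carry both unadjusted
and Tukey-adjusted (studentized-range) 95% CIs; non-inferiority of an
experimental arm holds iff the lower bound of the two-sided 95% CI of
the difference exceeds the margin (default −3.6 g/day, i.e. 10% of a
normal 36 g/day gain), with a one-sided p against H0: diff ≤ margin.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
import statsmodels.formula.api as smf

DEFAULT_MARGIN = -3.6  # g/day


# ---------------------------------------------------------------------------
# ANCOVA with Tukey-adjusted pairwise differences
# ---------------------------------------------------------------------------


def ancova_adjusted_means(
    data: pd.DataFrame,
    outcome: str = "weight_gain_g_day",
    group: str = "arm",
    baseline: str = "baseline_weight_kg",
    sex: str | None = "sex",
    alpha: float = 0.05,
) -> dict:
    """Least-squares adjusted group means and pairwise differences.

    Fits ``outcome ~ C(group) + baseline (+ C(sex))``; adjusted means are
    predictions at the covariate grand means.  Pairwise differences carry
    an unadjusted t CI and a Tukey CI using the studentized-range
    quantile at the residual degrees of freedom (Tukey-Kramer for
    unbalanced groups).  Rows with missing values are dropped (logged).
    """
    cols = [outcome, group, baseline] + ([sex] if sex else [])
    df = data[cols].dropna()
    if len(df) < len(data):
        warnings.warn(f"dropped {len(data) - len(df)} rows with missing values")
    levels = sorted(df[group].unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    formula = f"{outcome} ~ C({group}) + {baseline}" + (f" + C({sex})" if sex else "")
    fit = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("rank-deficient design; aliased columns in " + formula)
    k = len(levels)
    dfresid = int(fit.df_resid)

    # adjusted means: predict each group at covariate grand means
    grid = pd.DataFrame({group: levels})
    grid[baseline] = df[baseline].mean()
    if sex:
        # average over the observed sex distribution
        p_sex = df[sex].value_counts(normalize=True)
        preds = []
        for lv in levels:
            val = 0.0
            for s, w in p_sex.items():
                row = {group: lv, baseline: df[baseline].mean(), sex: s}
                val += w * float(fit.predict(pd.DataFrame([row])).iloc[0])
            preds.append(val)
    else:
        preds = [float(v) for v in fit.predict(grid)]
    tcrit = stats.t.ppf(1 - alpha / 2, dfresid)
    qcrit = stats.studentized_range.ppf(1 - alpha, k, dfresid)

    # group-mean SEs and pairwise contrasts via the coefficient covariance
    cov = fit.cov_params()
    names = fit.params.index
    means = {}
    for lv, pred in zip(levels, preds):
        means[lv] = {"mean": pred}
    comparisons = []
    for lv_b, lv_a in itertools.combinations(levels, 2):
        # difference lv_a - lv_b depends only on the group dummies
        vec = pd.Series(0.0, index=names)
        for nm in names:
            if nm == f"C({group})[T.{lv_a}]":
                vec[nm] = 1.0
            elif nm == f"C({group})[T.{lv_b}]":
                vec[nm] = -1.0
        est = float(vec @ fit.params)
        se = float(np.sqrt(vec @ cov @ vec))
        ci = (est - tcrit * se, est + tcrit * se)
        tukey_ci = (est - qcrit / math.sqrt(2) * se, est + qcrit / math.sqrt(2) * se)
        p_tukey = float(
            stats.studentized_range.sf(abs(est / se) * math.sqrt(2), k, dfresid)
        )
        comparisons.append(
            {
                "comparison": f"{lv_a} vs {lv_b}",
                "estimate": est,
                "se": se,
                "ci": ci,
                "tukey_ci": tukey_ci,
                "p_tukey": p_tukey,
                "df": dfresid,
            }
        )
    # per-group CI of the adjusted mean (SE via prediction at grand means)
    for lv in levels:
        sub = df[df[group] == lv]
        se_m = fit.mse_resid**0.5 / math.sqrt(len(sub))
        means[lv]["ci"] = (
            means[lv]["mean"] - tcrit * se_m,
            means[lv]["mean"] + tcrit * se_m,
        )
    return {
        "adjusted_means": means,
        "comparisons": comparisons,
        "df_resid": dfresid,
        "residual_sd": float(np.sqrt(fit.mse_resid)),
        "fit": fit,
    }


@dataclass
class NonInferiorityResult:
    comparison: str
    estimate: float
    ci: tuple[float, float]
    margin: float
    decision: bool
    p: float | None


def noninferiority_decision(
    ci: tuple[float, float],
    margin: float = DEFAULT_MARGIN,
    estimate: float | None = None,
    se: float | None = None,
    df: int | None = None,
    comparison: str = "",
) -> NonInferiorityResult:
    """Non-inferior iff the CI lower bound strictly exceeds the margin.

    When estimate/se/df from the ANCOVA fit are supplied, a one-sided p
    against H0: difference ≤ margin is attached.
    """
    lo, hi = ci
    decision = lo > margin
    p = None
    if estimate is not None and se is not None and se > 0:
        t = (estimate - margin) / se
        p = float(stats.t.sf(t, df) if df else stats.norm.sf(t))
    return NonInferiorityResult(comparison, estimate if estimate is not None else (lo + hi) / 2,
                                (lo, hi), margin, bool(decision), p)


def sample_size_noninferiority(
    margin: float = 3.6,
    sd: float = 7.7,
    alpha_one_sided: float = 0.025,
    power: float = 0.80,
    attrition: float = 0.03,
) -> dict:
    """Normal-approximation per-group n for a non-inferiority comparison.

    n0 = 2 (z_{1−α} + z_{power})² sd² / margin², rounded up, then
    inflated by 1/(1 − attrition) and rounded up again.
    """
    if margin == 0:
        raise ValueError("margin must be nonzero")
    if not 0 < power < 1 or sd <= 0:
        raise ValueError("invalid power or sd")
    z = stats.norm.ppf(1 - alpha_one_sided) + stats.norm.ppf(power)
    n0 = math.ceil(2 * z**2 * sd**2 / margin**2)
    n = math.ceil(n0 / (1 - attrition))
    return {"n_unadjusted": n0, "n_per_group": n}


def relative_risk(a: int, n1: int, b: int, n2: int) -> dict:
    """Risk ratio with a 95% log-normal CI.

    Zero event counts trigger the +0.5 continuity correction (flagged).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    corrected = False
    aa, bb, m1, m2 = a, b, n1, n2
    if a == 0 or b == 0:
        aa, bb, m1, m2 = a + 0.5, b + 0.5, n1 + 0.5, n2 + 0.5
        corrected = True
    rr = (aa / m1) / (bb / m2)
    se = math.sqrt(1 / aa - 1 / m1 + 1 / bb - 1 / m2)
    ci = (rr * math.exp(-1.959963984540054 * se), rr * math.exp(1.959963984540054 * se))
    return {"rr": rr, "ci": ci, "continuity_corrected": corrected}


# ---------------------------------------------------------------------------
# Freeman-Halton exact / Monte-Carlo test
# ---------------------------------------------------------------------------


def _log_table_prob(table: np.ndarray, logfac_rows, logfac_cols, logfac_n) -> float:
    return float(logfac_rows + logfac_cols - logfac_n - gammaln(table + 1).sum())


def _enumerate_tables(row_m, col_m):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_m), len(col_m)

    def rec(i, cols_left):
        if i == r - 1:
            yield [list(cols_left)]
            return
        for combo in _row_fills(row_m[i], cols_left):
            rest = tuple(cl - x for cl, x in zip(cols_left, combo))
            for tail in rec(i + 1, rest):
                yield [list(combo)] + tail

    def _row_fills(total, caps):
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        for x in range(min(total, caps[0]) + 1):
            for tail in _row_fills(total - x, caps[1:]):
                yield (x,) + tail

    yield from rec(0, tuple(col_m))


def freeman_halton_test(
    table: np.ndarray | pd.DataFrame,
    n_mc: int = 10000,
    seed: int | None = None,
    max_enumeration: int = 10**6,
) -> dict:
    """Exact (Freeman-Halton) test of independence for an r×c table.

    Tables with the observed margins are ordered by hypergeometric
    probability; the two-sided p sums the probabilities of all tables no
    more probable than the observed one.  Exact enumeration is used when
    the candidate-table count is manageable, else fixed-margin Monte
    Carlo with the add-one rule.  Degenerate margins give p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row_m = t.sum(axis=1)
    col_m = t.sum(axis=0)
    t = t[row_m > 0][:, col_m > 0]
    row_m = t.sum(axis=1)
    col_m = t.sum(axis=0)
    if t.size == 0 or t.shape[0] < 2 or t.shape[1] < 2:
        return {"p": 1.0, "method": "degenerate"}
    n = t.sum()
    logfac_rows = gammaln(row_m + 1).sum()
    logfac_cols = gammaln(col_m + 1).sum()
    logfac_n = gammaln(n + 1)
    obs_lp = _log_table_prob(t, logfac_rows, logfac_cols, logfac_n)
    # rough bound on the number of candidate tables
    bound = 1.0
    for rm in row_m[:-1]:
        bound *= math.comb(int(rm) + len(col_m) - 1, len(col_m) - 1)
    if bound <= max_enumeration:
        p = 0.0
        for cand in _enumerate_tables(list(row_m), list(col_m)):
            lp = _log_table_prob(np.asarray(cand), logfac_rows, logfac_cols, logfac_n)
            if lp <= obs_lp + 1e-9:
                p += math.exp(lp)
        return {"p": min(p, 1.0), "method": "exact"}
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(col_m)), col_m)
    row_of = np.repeat(np.arange(len(row_m)), row_m)
    hits = 0
    for _ in range(n_mc):
        sim = np.zeros_like(t)
        np.add.at(sim, (row_of, rng.permutation(labels)), 1)
        lp = _log_table_prob(sim, logfac_rows, logfac_cols, logfac_n)
        hits += lp <= obs_lp + 1e-9
    return {"p": (1 + hits) / (1 + n_mc), "method": "monte-carlo", "n_mc": n_mc}


# ---------------------------------------------------------------------------
# censoring and multiplicity
# ---------------------------------------------------------------------------


@dataclass
class CensoringRule:
    analyte: str
    lld: float
    lod: float


def apply_censoring(values: np.ndarray | pd.Series, rule: CensoringRule) -> dict:
    """Detection-limit handling for one analyte.

    If fewer than 10% of values fall below the LLD, those values are
    replaced by the LLD itself and modeling proceeds.  If more than 50%
    fall below the LOD, the analyte is flagged "no-model".  The in-between
    regime passes values through unmodified with a "caution" flag.
    """
    v = np.asarray(values, dtype=float)
    frac_lld = float((v < rule.lld).mean())
    frac_lod = float((v < rule.lod).mean())
    if frac_lod > 0.50:
        return {"values": v, "flag": "no-model", "frac_below_lld": frac_lld,
                "frac_below_lod": frac_lod}
    if frac_lld < 0.10:
        out = np.where(v < rule.lld, rule.lld, v)
        return {"values": out, "flag": "ok", "frac_below_lld": frac_lld,
                "frac_below_lod": frac_lod}
    return {"values": v, "flag": "caution", "frac_below_lld": frac_lld,
            "frac_below_lod": frac_lod}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs propagate, flagged)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if np.isnan(p).any():
        warnings.warn("NaN p-values propagated unadjusted")
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[mask] = res
    return out
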