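"""Statistical evaluation harness: reliability (ICC), group comparison with
BH-adjusted pairwise tests, ROC screening analysis, stepwise multivariable
logistic prediction, and between-arm testing of follow-up changes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import Logit, add_constant
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (ConvergenceWarning,
                                             PerfectSeparationWarning)

__all__ = [
    "ICCResult",
    "ROCResult",
    "StepwiseResult",
    "icc_absolute_single",
    "group_anova",
    "pairwise_bh",
    "roc_screen",
    "empirical_auc",
    "delong_ci",
    "binormal_auc",
    "stepwise_logistic",
    "shunt_change_test",
    "MEASURES",
]

MEASURES = ("EI", "CA", "SA")


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single measurement."""

    icc: float
    ci95: tuple[float, float]
    ms_rows: float
    ms_cols: float
    ms_error: float
    model: str = "ICC(A,1)"
    flagged: str | None = None


def icc_absolute_single(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC for absolute agreement of single measurements in a two-way model.

    ``ratings`` is a subjects x raters matrix with no missing cells. The
    point estimate is (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    from the two-way ANOVA mean squares, with the McGraw-Wong F-based 95% CI.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 raters")
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if np.isnan(x).any():
        raise ValueError("ratings must have no missing cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.isclose(msr, 0.0):
        return ICCResult(np.nan, (np.nan, np.nan), msr, msc, mse,
                         flagged="undefined: no between-subject variance")
    icc = (msr - mse) / denom

    # McGraw & Wong F-based interval for ICC(A,1)
    if np.isclose(mse, 0.0):
        lo = hi = icc  # perfect agreement: degenerate interval
    else:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = ((n - 1) * k ** 2 * icc ** 2 * fj ** 2
              + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
        v = vn / vd
        f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    lo, hi = min(lo, icc), max(hi, icc)
    return ICCResult(float(icc), (float(lo), float(hi)), float(msr), float(msc), float(mse))


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def _group_values(table: pd.DataFrame, measure: str) -> dict[str, np.ndarray]:
    if measure not in table.columns:
        raise KeyError(f"measure {measure!r} missing from the table")
    out = {g: sub[measure].to_numpy(dtype=float) for g, sub in table.groupby("group", sort=False)}
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def group_anova(table: pd.DataFrame, measure: str) -> tuple[float, float]:
    """One-way ANOVA F and p for one measure across the group column."""
    groups = _group_values(table, measure)
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("each group needs at least 2 observations")
    f, p = sps.f_oneway(*groups.values())
    return float(f), float(p)


def pairwise_bh(table: pd.DataFrame, measure: str,
                equal_var: bool = True) -> pd.DataFrame:
    """All pairwise two-sided t-tests with Benjamini-Hochberg adjustment.

    Returns a symmetric group x group matrix of BH-adjusted p-values (step-up
    over all pairs, enforcing the usual monotonicity), NaN on the diagonal.
    """
    groups = _group_values(table, measure)
    names = list(groups)
    pairs = list(combinations(names, 2))
    raw = np.array([sps.ttest_ind(groups[a], groups[b], equal_var=equal_var).pvalue
                    for a, b in pairs])
    adj = multipletests(raw, method="fdr_bh")[1] if len(raw) > 1 else raw.copy()
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), p in zip(pairs, adj):
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


# ---------------------------------------------------------------------------
# ROC screening
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """Empirical ROC summary at the closest-to-top-left cutoff."""

    auc: float
    ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    direction: str  # 'lower' (low score favors positive) or 'higher'


def empirical_auc(scores: np.ndarray, labels: np.ndarray,
                  direction: str = "higher") -> float:
    """Empirical AUC in the rank (Mann-Whitney) form, tie-aware."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if direction == "lower":
        s = -s
    elif direction != "higher":
        raise ValueError("direction must be 'lower' or 'higher'")
    n_pos, n_neg = y.sum(), (~y).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and variance via placement values (midranks for ties)."""
    m, n = len(pos), len(neg)
    all_s = np.concatenate([pos, neg])
    rk = sps.rankdata(all_s)
    rk_pos = sps.rankdata(pos)
    rk_neg = sps.rankdata(neg)
    auc = (rk[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rk[:m] - rk_pos) / n  # placement of each positive among negatives
    v01 = 1.0 - (rk[m:] - rk_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def delong_ci(scores: np.ndarray, labels: np.ndarray, direction: str = "higher",
              alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Empirical AUC with the DeLong 95% confidence interval, clipped to [0,1]."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if direction == "lower":
        s = -s
    auc, var = _delong_variance(s[y], s[~y])
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return auc, (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))


def roc_screen(scores: np.ndarray, labels: np.ndarray,
               direction: str = "higher") -> ROCResult:
    """ROC screening summary with the cutoff closest to the top-left corner.

    Candidate cutoffs are the observed score values; a score at or beyond the
    cutoff (in the positive-favoring direction) is called positive. The
    cutoff minimizes (1-sens)^2 + (1-spec)^2; ties go to the higher
    specificity, then to the more extreme cutoff. AUC CI is DeLong's.
    """
    s_raw = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("both classes must be present")
    s = -s_raw if direction == "lower" else s_raw
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")

    auc, ci = delong_ci(scores, labels, direction)
    thresholds = np.unique(s)
    n_pos, n_neg = y.sum(), (~y).sum()
    best = None
    for t in thresholds:
        pred = s >= t
        tp = (pred & y).sum()
        tn = (~pred & ~y).sum()
        sens = tp / n_pos
        spec = tn / n_neg
        d2 = (1 - sens) ** 2 + (1 - spec) ** 2
        key = (d2, -spec, -t)  # ties: higher specificity, then more extreme cutoff
        if best is None or key < best[0]:
            pv = tp / pred.sum() if pred.any() else np.nan
            nv = tn / (~pred).sum() if (~pred).any() else np.nan
            acc = (tp + tn) / len(y)
            best = (key, t, sens, spec, acc, pv, nv)
    _, t, sens, spec, acc, ppv, npv = best
    cutoff = -t if direction == "lower" else t
    return ROCResult(auc, ci, float(cutoff), float(sens), float(spec), float(acc),
                     float(ppv), float(npv), direction)


def binormal_auc(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float,
                 direction: str = "lower") -> float:
    """Closed-form AUC for two Gaussian score distributions.

    With lower scores favoring the positive class the AUC is
    Phi((mu_neg - mu_pos) / sqrt(sd_pos^2 + sd_neg^2)); the separation sign
    flips for 'higher'. Degenerate zero-SD case returns 1, 0, or 0.5 by the
    ordering of the means.
    """
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    sep = (mu_neg - mu_pos) if direction == "lower" else (mu_pos - mu_neg)
    rss = float(np.hypot(sd_pos, sd_neg))
    if rss == 0.0:
        return 0.5 if sep == 0 else (1.0 if sep > 0 else 0.0)
    return float(sps.norm.cdf(sep / rss))


# ---------------------------------------------------------------------------
# Stepwise multivariable prediction
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    selected: list[str]
    model_aucs: dict[str, tuple[float, tuple[float, float]]]
    trace: list[tuple[str, str, float]] = field(default_factory=list)
    separation_flagged: bool = False


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> tuple[np.ndarray, float, bool]:
    """Fit a logistic model; fall back to a ridge-penalized fit under
    (quasi-)separation. Returns (predicted probs, AIC-style criterion, flagged)."""
    Xc = add_constant(X, has_constant="add")
    flagged = False
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = Logit(y, Xc).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 50:
            raise RuntimeError("separation suspected")
        p = np.asarray(res.predict(Xc))
        llf = float(res.llf)
    except Exception:
        flagged = True
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = Logit(y, Xc).fit_regularized(disp=0, alpha=1.0, maxiter=500)
        p = np.asarray(res.predict(Xc))
        eps = 1e-12
        llf = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    aic = 2 * Xc.shape[1] - 2 * llf
    return p, aic, flagged


def stepwise_logistic(table: pd.DataFrame, candidates: tuple[str, ...] = MEASURES,
                      positive_group: str = "NPH") -> StepwiseResult:
    """Bidirectional AIC stepwise logistic regression predicting the positive
    group from the pooled remaining groups, starting from the full model.

    Also reports in-sample AUC (+ DeLong CI) for the six fixed models of the
    comparison layout: each single index, SA+EI, SA+CA, and all three.
    """
    y = (table["group"] == positive_group).to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("outcome must contain both classes")
    for c in candidates:
        if c not in table.columns:
            raise KeyError(f"candidate {c!r} missing from the table")

    flagged = False
    current = list(candidates)
    _, current_aic, f = _fit_logit(y, table[current])
    flagged |= f
    trace: list[tuple[str, str, float]] = [("start", "+".join(current), current_aic)]
    while True:
        moves = []
        for term in current:
            sub = [t for t in current if t != term]
            if sub:
                _, aic, f = _fit_logit(y, table[sub])
            else:
                p0 = np.full_like(y, y.mean())
                llf0 = float(np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0)))
                aic, f = 2 - 2 * llf0, False
            moves.append(("drop", term, aic, f))
        for term in candidates:
            if term not in current:
                _, aic, f = _fit_logit(y, table[current + [term]])
                moves.append(("add", term, aic, f))
        moves.sort(key=lambda m: m[2])
        action, term, aic, f = moves[0]
        if aic >= current_aic - 1e-9:
            break
        flagged |= f
        current = ([t for t in current if t != term] if action == "drop"
                   else current + [term])
        current_aic = aic
        trace.append((action, term, aic))

    layouts = [("EI",), ("CA",), ("SA",), ("SA", "EI"), ("SA", "CA"), ("EI", "CA", "SA")]
    model_aucs: dict[str, tuple[float, tuple[float, float]]] = {}
    for terms in layouts:
        terms = tuple(t for t in terms if t in table.columns)
        p, _, f = _fit_logit(y, table[list(terms)])
        flagged |= f
        auc, ci = delong_ci(p, y.astype(bool), "higher")
        model_aucs[" + ".join(terms)] = (auc, ci)
    return StepwiseResult(sorted(current), model_aucs, trace, flagged)


# ---------------------------------------------------------------------------
# Follow-up changes
# ---------------------------------------------------------------------------

def shunt_change_test(followup: pd.DataFrame, equal_var: bool = True) -> pd.DataFrame:
    """Between-arm Student's t-test on per-measure deltas.

    Expects the paired table from ``simulate_followup`` (columns dEI/dCA/dSA
    plus ``arm``); returns one row per measure with per-arm mean +- SD and the
    two-sided p-value.
    """
    arms = followup.groupby("arm", sort=False)
    if len(arms) != 2:
        raise ValueError("need exactly two arms")
    names = list(arms.groups)
    rows = []
    for m in MEASURES:
        col = f"d{m}"
        if col not in followup.columns:
            raise KeyError(f"missing delta column {col!r}")
        a = arms.get_group(names[0])[col].to_numpy(dtype=float)
        b = arms.get_group(names[1])[col].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each arm needs at least 2 subjects")
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        rows.append({"measure": m,
                     f"mean_{names[0]}": a.mean(), f"sd_{names[0]}": a.std(ddof=1),
                     f"mean_{names[1]}": b.mean(), f"sd_{names[1]}": b.std(ddof=1),
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)
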