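"""Cohort-level concordance and discrimination statistics.

Given paired estimates (per-vessel FFR from the bench pipeline vs a
reference, e.g. invasive FFR), this module computes the standard method-
comparison suite: Spearman rank correlation, a paired t-test on the means,
Bland–Altman bias with 95% limits of agreement and a proportional-bias
test, and ROC analysis against the ischemia reference standard
(reference FFR <= 0.80), with the Youden-optimal threshold, DeLong
confidence interval for the AUC and Clopper–Pearson exact intervals for
sensitivity and specificity.

A *positive* (ischemic) vessel is one with reference FFR <= cutoff, and a
vessel is *predicted* positive when the estimated FFR <= threshold — lower
values indicate more severe disease throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConcordanceReport",
    "ROCReport",
    "spearman",
    "spearman_exact_p",
    "bland_altman",
    "compare_means",
    "roc_analysis",
    "clopper_pearson",
    "concordance_report",
]


class DegenerateStatisticError(ValueError):
    """Statistic undefined on this input (constant ranks, one class, ...)."""


@dataclass(frozen=True)
class ConcordanceReport:
    n: int
    spearman_r: float
    spearman_p: float
    mean_ffr3d: float
    sd_ffr3d: float
    mean_ref: float
    sd_ref: float
    paired_p: float
    bias: float
    loa_low: float
    loa_high: float
    proportional_bias_r: float
    proportional_bias_p: float


@dataclass(frozen=True)
class ROCReport:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    optimal_threshold: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    reference_cutoff: float
    n_positive: int
    n_negative: int


def _paired_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        x = pairs["ffr3d"].to_numpy(dtype=float)
        y = pairs["ffr_ref"].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in paired data")
    return x, y


def spearman(pairs, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    ``method='t'`` uses the t-distribution approximation for the p-value;
    ``method='exact'`` enumerates all rank permutations (n <= 8 only).
    """
    x, y = _paired_arrays(pairs)
    if x.size < 3:
        raise DegenerateStatisticError("need n >= 3 pairs for a rank correlation")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateStatisticError("correlation undefined for constant input")
    r, p = sps.spearmanr(x, y)
    if method == "exact":
        p = spearman_exact_p(x, y)
    elif method != "t":
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def spearman_exact_p(x, y) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (n <= 8)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 8:
        raise ValueError("exact enumeration limited to n <= 8")
    r_obs = abs(sps.spearmanr(x, y).statistic)
    rx = sps.rankdata(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(sps.spearmanr(rx, y[list(perm)]).statistic)
        count += r >= r_obs - 1e-12
        total += 1
    return count / total


def bland_altman(pairs) -> dict:
    """Bias and 95% limits of agreement of the paired differences.

    Differences d = ffr3d − ffr_ref; bias = mean(d); limits of agreement
    bias ± 1.96·sd(d) with the sample sd (ddof=1).  Proportional bias is the
    Spearman correlation of d against the pair means.
    """
    x, y = _paired_arrays(pairs)
    if x.size < 2:
        raise DegenerateStatisticError("need n >= 2 pairs for limits of agreement")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    means = (x + y) / 2.0
    if np.unique(d).size == 1 or np.unique(means).size == 1:
        prop_r, prop_p = float("nan"), float("nan")
    else:
        res = sps.spearmanr(d, means)
        prop_r, prop_p = float(res.statistic), float(res.pvalue)
    return {
        "bias": bias,
        "sd_diff": sd,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "proportional_bias_r": prop_r,
        "proportional_bias_p": prop_p,
    }


def compare_means(pairs) -> float:
    """Two-sided paired t-test p-value for equality of the means."""
    x, y = _paired_arrays(pairs)
    if x.size < 2:
        raise DegenerateStatisticError("need n >= 2 pairs for a paired test")
    d = x - y
    if np.allclose(np.std(d, ddof=0), 0.0):
        raise DegenerateStatisticError("paired t-test degenerate: zero-variance differences")
    return float(sps.ttest_rel(x, y).pvalue)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided CI for a binomial proportion."""
    if not 0 <= k <= n or n == 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _auc_mann_whitney(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC as P(score_pos < score_neg) + ½·P(tie): lower score = more diseased."""
    all_scores = np.concatenate([pos_scores, neg_scores])
    ranks = sps.rankdata(all_scores)
    n1, n0 = pos_scores.size, neg_scores.size
    # Sum of positive ranks counts (pos > neg) pairs; AUC orients lower-positive.
    r_pos = float(np.sum(ranks[:n1]))
    u_greater = r_pos - n1 * (n1 + 1) / 2.0
    return 1.0 - u_greater / (n1 * n0)


def _delong_ci(pos_scores, neg_scores, auc, alpha=0.05):
    """DeLong variance of the AUC via placement values; Wald CI clipped to [0,1]."""
    # Orient so that higher value = positive class, matching the standard derivation.
    x = -np.asarray(pos_scores, dtype=float)
    y = -np.asarray(neg_scores, dtype=float)
    m, n = x.size, y.size
    v10 = np.array([(np.sum(xi > y) + 0.5 * np.sum(xi == y)) / n for xi in x])
    v01 = np.array([(np.sum(x > yj) + 0.5 * np.sum(x == yj)) / m for yj in y])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = float(sps.norm.ppf(1 - alpha / 2))
    return max(0.0, auc - z * se), min(1.0, auc + z * se)


def roc_analysis(pairs, reference_cutoff: float = 0.80) -> ROCReport:
    """Empirical ROC of the FFR estimate against the dichotomized reference.

    Thresholds sweep the distinct estimated values; the Youden-optimal one
    maximizes sensitivity + specificity − 1, ties broken toward higher
    specificity (the stricter, lower threshold).
    """
    x, y = _paired_arrays(pairs)
    labels = y <= reference_cutoff
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateStatisticError(
            "no discrimination defined: reference contains a single class at "
            f"cutoff {reference_cutoff:g}"
        )
    pos, neg = x[labels], x[~labels]
    auc = _auc_mann_whitney(pos, neg)
    ci_lo, ci_hi = _delong_ci(pos, neg, auc)

    best = None
    for t in np.unique(x):
        sens = float(np.mean(pos <= t))
        spec = float(np.mean(neg > t))
        j = sens + spec - 1.0
        # Ties on Youden's J resolved toward higher specificity; remaining
        # ties toward the lower threshold (stricter call).
        key = (j, spec, -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, t_opt, sens, spec = best
    k_sens = int(round(sens * n1))
    k_spec = int(round(spec * n0))
    return ROCReport(
        auc=float(auc),
        auc_ci_low=ci_lo,
        auc_ci_high=ci_hi,
        optimal_threshold=float(t_opt),
        sensitivity=sens,
        sensitivity_ci=clopper_pearson(k_sens, n1),
        specificity=spec,
        specificity_ci=clopper_pearson(k_spec, n0),
        reference_cutoff=reference_cutoff,
        n_positive=n1,
        n_negative=n0,
    )


def concordance_report(pairs) -> ConcordanceReport:
    """Full agreement panel for paired (ffr3d, ffr_ref) values."""
    x, y = _paired_arrays(pairs)
    r, p = spearman(pairs)
    ba = bland_altman(pairs)
    try:
        paired_p = compare_means(pairs)
    except DegenerateStatisticError:
        paired_p = float("nan")
    return ConcordanceReport(
        n=int(x.size),
        spearman_r=r,
        spearman_p=p,
        mean_ffr3d=float(np.mean(x)),
        sd_ffr3d=float(np.std(x, ddof=1)),
        mean_ref=float(np.mean(y)),
        sd_ref=float(np.std(y, ddof=1)),
        paired_p=paired_p,
        bias=ba["bias"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        proportional_bias_r=ba["proportional_bias_r"],
        proportional_bias_p=ba["proportional_bias_p"],
    )
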