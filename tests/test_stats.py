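"""Concordance and ROC statistics validated against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ffrbench.stats import (
    DegenerateStatisticError,
    bland_altman,
    clopper_pearson,
    compare_means,
    concordance_report,
    roc_analysis,
    spearman,
    spearman_exact_p,
)


def _pairs(x, y):
    return pd.DataFrame({"ffr3d": x, "ffr_ref": y})


class TestSpearman:
    def test_perfect_monotone(self):
        r, _ = spearman(_pairs([0.5, 0.6, 0.7, 0.8], [0.4, 0.55, 0.72, 0.9]))
        assert r == pytest.approx(1.0)

    def test_reversed_ranks(self):
        r, _ = spearman(_pairs([0.5, 0.6, 0.7, 0.8], [0.9, 0.72, 0.55, 0.4]))
        assert r == pytest.approx(-1.0)

    def test_six_pair_toy_against_manual_ranking(self):
        # x ranks: 1 2 3 4 5 6 ; y = (0.3,0.1,0.4,0.2,0.6,0.5) ranks 3 1 4 2 6 5
        # d = (-2,1,-1,2,-1,1), sum d^2 = 12; rho = 1 - 6*12/(6*35) = 0.657142...
        x = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        y = [0.3, 0.1, 0.4, 0.2, 0.6, 0.5]
        r, _ = spearman(_pairs(x, y))
        assert r == pytest.approx(1 - 72 / 210, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            spearman(_pairs([0.5, 0.5, 0.5], [0.4, 0.6, 0.7]))

    def test_exact_permutation_p_matches_enumeration_definition(self):
        x = [0.1, 0.2, 0.3, 0.4, 0.5]
        y = [0.15, 0.1, 0.45, 0.3, 0.5]
        p = spearman_exact_p(np.array(x), np.array(y))
        # brute force over all 120 permutations of y
        r_obs = abs(sps.spearmanr(x, y).statistic)
        count = sum(
            abs(sps.spearmanr(x, np.array(y)[list(perm)]).statistic) >= r_obs - 1e-12
            for perm in itertools.permutations(range(5))
        )
        assert p == pytest.approx(count / 120)


class TestBlandAltman:
    def test_identical_pairs(self):
        out = bland_altman(_pairs([0.7, 0.8, 0.9], [0.7, 0.8, 0.9]))
        assert out["bias"] == 0.0
        assert out["loa_low"] == 0.0 and out["loa_high"] == 0.0

    def test_hand_arithmetic_two_pairs(self):
        # d = {+0.1, -0.1}: bias 0, sd = 0.1*sqrt(2), LOA = +/-1.96*sd
        out = bland_altman(_pairs([0.8, 0.6], [0.7, 0.7]))
        assert out["bias"] == pytest.approx(0.0, abs=1e-15)
        assert out["sd_diff"] == pytest.approx(0.1 * np.sqrt(2), rel=1e-12)
        assert out["loa_high"] == pytest.approx(1.96 * 0.1 * np.sqrt(2), rel=1e-12)
        assert out["loa_high"] == pytest.approx(0.277, abs=5e-4)
        assert out["loa_low"] == pytest.approx(-out["loa_high"], rel=1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.4, 0.9, 20)
        y = rng.uniform(0.4, 0.9, 20)
        base = bland_altman(_pairs(x, y))
        shifted = bland_altman(_pairs(x + 0.05, y))
        assert shifted["bias"] == pytest.approx(base["bias"] + 0.05, rel=1e-9)
        width = base["loa_high"] - base["loa_low"]
        assert shifted["loa_high"] - shifted["loa_low"] == pytest.approx(width, rel=1e-9)

    def test_loa_cover_about_95_percent_of_gaussian_differences(self):
        rng = np.random.default_rng(42)
        y = rng.uniform(0.5, 0.9, 5000)
        x = y + rng.normal(0.0, 0.05, 5000)
        out = bland_altman(_pairs(x, y))
        d = x - y
        covered = np.mean((d >= out["loa_low"]) & (d <= out["loa_high"]))
        assert covered == pytest.approx(0.95, abs=0.01)


class TestCompareMeans:
    def test_identical_pairs_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            compare_means(_pairs([0.7, 0.8], [0.7, 0.8]))

    def test_symmetric_differences_give_p_one(self):
        p = compare_means(_pairs([0.7, 0.9, 0.6, 0.8], [0.8, 0.8, 0.7, 0.7]))
        assert p == pytest.approx(1.0)

    def test_five_pair_toy_against_closed_form_t(self):
        x = np.array([0.70, 0.75, 0.80, 0.85, 0.90])
        y = np.array([0.68, 0.70, 0.79, 0.80, 0.95])
        d = x - y
        t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_expected = 2 * sps.t.sf(abs(t), df=4)
        assert compare_means(_pairs(x, y)) == pytest.approx(p_expected, rel=1e-12)


class TestClopperPearson:
    @pytest.mark.parametrize("k,n", [(0, 10), (10, 10), (13, 15), (7, 28)])
    def test_interval_inverts_binomial_tails(self, k, n):
        lo, hi = clopper_pearson(k, n)
        assert lo <= k / n <= hi
        if 0 < k:
            assert sps.binom.sf(k - 1, n, lo) == pytest.approx(0.025, rel=1e-6)
        if k < n:
            assert sps.binom.cdf(k, n, hi) == pytest.approx(0.025, rel=1e-6)

    def test_known_value(self):
        # 13/15 successes: the classic exact interval 59.5%..98.3%
        lo, hi = clopper_pearson(13, 15)
        assert lo == pytest.approx(0.595, abs=5e-4)
        assert hi == pytest.approx(0.983, abs=5e-4)


def _brute_force_auc(x, labels):
    pos = x[labels]
    neg = x[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p < q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        x = [0.5, 0.55, 0.6, 0.85, 0.9, 0.95]
        y = [0.6, 0.7, 0.75, 0.85, 0.9, 0.95]
        rep = roc_analysis(_pairs(x, y))
        assert rep.auc == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_uninformative_scores_give_half(self):
        x = [0.7] * 8
        y = [0.6, 0.65, 0.7, 0.75, 0.85, 0.9, 0.95, 0.82]
        rep = roc_analysis(_pairs(x, y))
        assert rep.auc == pytest.approx(0.5)

    def test_ten_pair_toy_against_exhaustive_pair_counting(self):
        x = np.array([0.55, 0.62, 0.71, 0.74, 0.77, 0.79, 0.82, 0.85, 0.88, 0.74])
        y = np.array([0.60, 0.72, 0.78, 0.70, 0.81, 0.79, 0.84, 0.83, 0.90, 0.86])
        rep = roc_analysis(_pairs(x, y))
        labels = y <= 0.80
        assert rep.auc == pytest.approx(_brute_force_auc(x, labels), abs=1e-12)

    def test_single_class_reference_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            roc_analysis(_pairs([0.5, 0.6, 0.7], [0.9, 0.95, 0.85]))

    def test_sensitivity_specificity_recompute_from_confusion_matrix(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(0.5, 1.0, 40)
        x = np.clip(y + rng.normal(0, 0.08, 40), 0.3, 1.0)
        rep = roc_analysis(_pairs(x, y))
        labels = y <= 0.80
        pred = x <= rep.optimal_threshold
        sens = np.sum(pred & labels) / np.sum(labels)
        spec = np.sum(~pred & ~labels) / np.sum(~labels)
        assert rep.sensitivity == pytest.approx(sens)
        assert rep.specificity == pytest.approx(spec)

    def test_youden_ties_break_toward_higher_specificity(self):
        # J = 0.5 both at t = 0.60 (sens 1/2, spec 1) and at t = 0.85
        # (sens 1, spec 1/2); the tie must resolve to the spec-1 threshold.
        x = [0.60, 0.75, 0.85, 0.90]
        y = [0.70, 0.90, 0.78, 0.95]  # labels: pos, neg, pos, neg
        rep = roc_analysis(_pairs(x, y))
        assert rep.optimal_threshold == pytest.approx(0.60)
        assert rep.specificity == 1.0

    def test_delong_ci_matches_reference_implementation(self):
        """Frozen oracle: pROC ci.auc(..., method='delong') on this toy set."""
        x = [0.55, 0.62, 0.66, 0.70, 0.74, 0.77, 0.79, 0.81, 0.83, 0.85, 0.88, 0.91, 0.72, 0.86]
        y = [0.52, 0.60, 0.70, 0.65, 0.72, 0.78, 0.82, 0.79, 0.84, 0.86, 0.90, 0.93, 0.81, 0.77]
        rep = roc_analysis(_pairs(x, y))
        assert rep.auc == pytest.approx(0.8333333333, abs=1e-9)
        assert rep.auc_ci_low == pytest.approx(0.6111800639, abs=1e-9)
        assert rep.auc_ci_high == pytest.approx(1.0, abs=1e-9)

    def test_auc_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        y = rng.uniform(0.4, 1.0, 60)
        x = np.clip(y + rng.normal(0, 0.1, 60), 0.2, 1.1)
        rep = roc_analysis(_pairs(x, y))
        labels = (y <= 0.80).astype(int)
        assert rep.auc == pytest.approx(roc_auc_score(labels, -x), abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0.2, 1.0, allow_nan=False), min_size=4, max_size=30),
    st.integers(0, 2**31 - 1),
)
def test_property_trapezoid_auc_equals_pair_counting(values, seed):
    """Mann–Whitney AUC == trapezoidal area under the empirical ROC curve."""
    rng = np.random.default_rng(seed)
    x = np.round(np.array(values), 3)
    labels = rng.random(x.size) < 0.5
    if labels.all() or not labels.any():
        return
    rep = roc_analysis(_pairs(x, np.where(labels, 0.5, 0.95)))
    # empirical ROC traced over thresholds, integrated with the trapezoid rule
    thresholds = np.concatenate([[-np.inf], np.unique(x), [np.inf]])
    pos, neg = x[labels], x[~labels]
    tpr = [np.mean(pos <= t) for t in thresholds]
    fpr = [np.mean(neg <= t) for t in thresholds]
    auc_trap = np.trapezoid(tpr, fpr)
    assert rep.auc == pytest.approx(auc_trap, abs=1e-10)


def test_concordance_report_is_consistent_with_components():
    rng = np.random.default_rng(5)
    y = rng.uniform(0.45, 0.95, 25)
    x = np.clip(y + rng.normal(0.01, 0.05, 25), 0.3, 1.0)
    pairs = _pairs(x, y)
    rep = concordance_report(pairs)
    r, p = spearman(pairs)
    ba = bland_altman(pairs)
    assert rep.spearman_r == r and rep.spearman_p == p
    assert rep.bias == ba["bias"] and rep.loa_high == ba["loa_high"]
    assert rep.n == 25
    assert rep.loa_low <= rep.bias <= rep.loa_high
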