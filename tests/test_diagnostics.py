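"""ROC/DeLong/bootstrap/permutation/calibration against brute-force oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from inpheld.diagnostics import (
    DiagnosticsError,
    ResamplingConfig,
    auc,
    calibration_slope,
    confusion_metrics,
    delong_test,
    delong_variance,
    mean_calibration_error,
    metrics_from_rates,
    permutation_pvalue,
    pre_post_comparison,
    roc_curve,
    spiegelhalter_test,
    stratified_bootstrap_ci,
    youden_cutoff,
)


# ----------------------------- oracles -------------------------------------

def brute_auc(scores, labels):
    """Pairwise Mann-Whitney definition with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_youden(scores, labels):
    """Exhaustive search over all midpoints plus outer sentinels."""
    uniq = np.unique(scores)
    cands = [uniq[0] - 1.0] + list((uniq[:-1] + uniq[1:]) / 2.0) + [uniq[-1] + 1.0]
    best = -np.inf
    for c in cands:
        sens = np.mean(scores[labels == 1] >= c)
        spec = np.mean(scores[labels == 0] < c)
        best = max(best, sens + spec - 1.0)
    return best


def brute_delong_variance(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    v10 = np.array([np.mean([1.0 if p > q else 0.5 if p == q else 0.0
                             for q in neg]) for p in pos])
    v01 = np.array([np.mean([1.0 if p > q else 0.5 if p == q else 0.0
                             for p in pos]) for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def random_instance(rng, n_max=30, tie_prone=True):
    n = int(rng.integers(4, n_max + 1))
    while True:
        labels = (rng.uniform(size=n) < 0.5).astype(int)
        if 0 < labels.sum() < n:
            break
    scores = rng.integers(0, 6, size=n).astype(float) if tie_prone \
        else rng.normal(size=n)
    return scores, labels


# ------------------------------ AUC -----------------------------------------

def test_auc_examples_and_symmetry():
    assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
    assert auc([1, 1, 2, 2], [0, 1, 0, 1]) == 0.5
    scores = np.array([0.1, 0.4, 0.4, 0.8, 0.9])
    labels = np.array([0, 1, 0, 1, 0])
    assert auc(scores, 1 - labels) == pytest.approx(1 - auc(scores, labels))


def test_auc_matches_bruteforce_with_ties(rng):
    for _ in range(150):
        scores, labels = random_instance(rng)
        assert auc(scores, labels) == brute_auc(scores, labels)


def test_auc_rejects_single_class():
    with pytest.raises(DiagnosticsError):
        auc([1.0, 2.0], [1, 1])


def test_sklearn_cross_check(rng):
    from sklearn.metrics import roc_auc_score
    for _ in range(20):
        scores, labels = random_instance(rng, tie_prone=False)
        assert auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


# ------------------------------ ROC curve / Youden ---------------------------

def test_roc_curve_endpoints_and_monotonicity(rng):
    scores, labels = random_instance(rng)
    curve = roc_curve(scores, labels)
    assert curve.sensitivity[0] == 1.0 and curve.specificity[0] == 0.0
    assert curve.sensitivity[-1] == 0.0 and curve.specificity[-1] == 1.0
    assert np.all(np.diff(curve.sensitivity) <= 0)
    assert np.all(np.diff(curve.specificity) >= 0)


def test_youden_scan_equals_exhaustive_search(rng):
    for _ in range(150):
        scores, labels = random_instance(rng)
        cutoff, j = youden_cutoff(scores, labels)
        assert j == pytest.approx(brute_youden(scores, labels), abs=1e-12)
        # the returned cutoff must actually achieve the returned J
        sens = np.mean(scores[labels == 1] >= cutoff)
        spec = np.mean(scores[labels == 0] < cutoff)
        assert sens + spec - 1.0 == pytest.approx(j, abs=1e-12)


def test_youden_perfect_separation_and_translation():
    scores = np.array([1.0, 2.0, 5.0, 6.0])
    labels = np.array([0, 0, 1, 1])
    cutoff, j = youden_cutoff(scores, labels)
    assert j == 1.0 and 2.0 < cutoff < 5.0
    shifted, j2 = youden_cutoff(scores + 10.0, labels)
    assert j2 == j and shifted == pytest.approx(cutoff + 10.0)


def test_youden_degenerate_scores():
    cutoff, j = youden_cutoff([3.0, 3.0, 3.0], [0, 1, 0])
    assert j == 0.0


# ------------------------------ confusion ------------------------------------

def test_confusion_metrics_bruteforce(rng):
    for _ in range(100):
        scores, labels = random_instance(rng)
        cutoff = float(rng.uniform(-1, 6))
        m = confusion_metrics(scores, labels, cutoff)
        tp = sum(1 for s, l in zip(scores, labels) if s >= cutoff and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= cutoff and l == 0)
        fn = sum(1 for s, l in zip(scores, labels) if s < cutoff and l == 1)
        tn = sum(1 for s, l in zip(scores, labels) if s < cutoff and l == 0)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (tp, fp, fn, tn)
        assert m["tp"] + m["fp"] + m["fn"] + m["tn"] == len(scores)
        assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
        if tp + fp:
            assert m["ppv"] == pytest.approx(tp / (tp + fp))


def test_confusion_all_correct_and_npv_identity():
    m = confusion_metrics([1.0, 2.0, 8.0, 9.0], [0, 0, 1, 1], 5.0)
    assert m["sensitivity"] == m["specificity"] == m["ppv"] == m["npv"] == 1.0
    m = confusion_metrics([5.0, 6.0, 7.0, 1.0], [1, 1, 0, 0], 4.0)
    assert m["fn"] == 0 and m["npv"] == 1.0


# ------------------------------ metrics_from_rates ---------------------------

def test_metrics_from_rates_traditional_battery():
    m = metrics_from_rates(0.400, 0.706, n_pos=5, n_neg=34)
    assert (m["tp"], m["fn"], m["tn"], m["fp"]) == (2, 3, 24, 10)
    assert m["ppv"] == pytest.approx(2 / 12)
    assert m["npv"] == pytest.approx(24 / 27)


def test_metrics_from_rates_combined_digital():
    m = metrics_from_rates(1.000, 0.794, n_pos=5, n_neg=34)
    assert (m["tp"], m["fn"], m["tn"], m["fp"]) == (5, 0, 27, 7)
    assert m["ppv"] == pytest.approx(5 / 12)
    assert m["npv"] == 1.0


def test_metrics_from_rates_perfect_and_inconsistent():
    m = metrics_from_rates(1.0, 1.0, n_pos=7, n_neg=13)
    assert m["ppv"] == 1.0 and m["npv"] == 1.0
    with pytest.raises(DiagnosticsError, match="no unique"):
        metrics_from_rates(0.333, 0.5, n_pos=2, n_neg=4)  # no tp/2 rounds to .333


def test_metrics_from_rates_satisfies_identities(rng):
    from decimal import ROUND_HALF_UP, Decimal

    def half_up(x):  # the printed-precision rounding convention
        return float(Decimal(repr(x)).quantize(Decimal("0.001"),
                                               rounding=ROUND_HALF_UP))

    for _ in range(50):
        n_pos = int(rng.integers(2, 40))
        n_neg = int(rng.integers(2, 40))
        tp = int(rng.integers(0, n_pos + 1))
        tn = int(rng.integers(0, n_neg + 1))
        m = metrics_from_rates(half_up(tp / n_pos), half_up(tn / n_neg),
                               n_pos, n_neg)
        assert m["tp"] + m["fn"] == n_pos and m["tn"] + m["fp"] == n_neg
        assert m["sensitivity"] == m["tp"] / n_pos


# ------------------------------ DeLong ---------------------------------------

def test_delong_identical_scores_gives_z0_p1(rng):
    scores, labels = random_instance(rng)
    z, p = delong_test(scores, scores, labels)
    assert z == 0.0 and p == 1.0


def test_delong_variance_matches_bruteforce(rng):
    for _ in range(100):
        scores, labels = random_instance(rng, n_max=20)
        assert delong_variance(scores, labels) == pytest.approx(
            brute_delong_variance(scores, labels), abs=1e-10)


def test_delong_antisymmetric(rng):
    scores, labels = random_instance(rng, tie_prone=False)
    other = np.asarray(scores) + rng.normal(size=len(scores))
    z_ab, p_ab = delong_test(scores, other, labels)
    z_ba, p_ba = delong_test(other, scores, labels)
    assert z_ab == pytest.approx(-z_ba)
    assert p_ab == pytest.approx(p_ba)


# ------------------------------ bootstrap ------------------------------------

def test_bootstrap_constant_statistic_zero_width(rng):
    labels = np.array([0] * 10 + [1] * 5)
    lo, hi, failed = stratified_bootstrap_ci(
        lambda idx: 3.14, labels, ResamplingConfig(bootstrap_B=50, seed=1))
    assert lo == hi == 3.14 and failed == 0


def test_bootstrap_ci_contains_point_estimate_for_mean(rng):
    x = rng.normal(size=40)
    labels = (rng.uniform(size=40) < 0.3).astype(int)
    lo, hi, _ = stratified_bootstrap_ci(
        lambda idx: float(np.mean(x[idx])), labels,
        ResamplingConfig(bootstrap_B=2000, seed=2))
    assert lo <= x.mean() <= hi


def test_bootstrap_stratified_never_loses_rare_class(rng):
    labels = np.array([0] * 34 + [1] * 5)
    scores = rng.normal(size=39) + labels
    lo, hi, failed = stratified_bootstrap_ci(
        lambda idx: auc(scores[idx], labels[idx]), labels,
        ResamplingConfig(bootstrap_B=300, seed=3))
    assert failed == 0 and 0.0 <= lo <= hi <= 1.0


def test_bootstrap_auc_coverage_near_nominal():
    """Percentile-bootstrap coverage for the AUC at the study's class sizes
    (5 vs 34) sits a little below nominal; accept a documented wide band."""
    true_auc_rng = np.random.default_rng(99)
    covered = 0
    reps = 120
    delta = 1.2  # score shift between classes
    # population AUC for N(0,1) vs N(delta,1): Phi(delta/sqrt(2))
    target = stats.norm.cdf(delta / math.sqrt(2))
    for k in range(reps):
        labels = np.array([0] * 34 + [1] * 5)
        scores = true_auc_rng.normal(size=39) + delta * labels
        lo, hi, _ = stratified_bootstrap_ci(
            lambda idx: auc(scores[idx], labels[idx]), labels,
            ResamplingConfig(bootstrap_B=400, seed=k))
        covered += lo <= target <= hi
    assert 0.80 <= covered / reps <= 0.99


# ------------------------------ permutation ----------------------------------

def test_permutation_pvalue_bounds_and_null_case(rng):
    n = 60
    x = rng.normal(size=n)
    y = (rng.uniform(size=n) < 0.4).astype(int)
    X = np.column_stack([np.ones(n), x])
    cfg = ResamplingConfig(permutation_B=99, seed=5)
    p, stat, bad = permutation_pvalue(X, X[:, :1], y, cfg)
    assert 1 / 100 <= p <= 1.0
    assert stat >= 0.0


def test_permutation_detects_strong_effect():
    rng = np.random.default_rng(11)
    n = 120
    x = rng.normal(size=n)
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(2.0 * x)))).astype(int)
    X = np.column_stack([np.ones(n), x])
    p, _, _ = permutation_pvalue(X, X[:, :1], y,
                                 ResamplingConfig(permutation_B=199, seed=6))
    assert p == pytest.approx(1 / 200)


# ------------------------------ calibration ----------------------------------

def test_spiegelhalter_half_probs_give_zero():
    z, p = spiegelhalter_test([0.5] * 20, [0, 1] * 10)
    assert z == 0.0 and p == 1.0


def test_spiegelhalter_flags_overconfidence():
    rng = np.random.default_rng(4)
    q = 1 / (1 + np.exp(-rng.normal(0, 1, size=1500)))
    y = (rng.uniform(size=1500) < q).astype(int)
    # push probabilities toward 0/1: overconfident
    over = 1 / (1 + np.exp(-3 * np.log(q / (1 - q))))
    z_ok, _ = spiegelhalter_test(q, y)
    z_bad, p_bad = spiegelhalter_test(over, y)
    assert abs(z_ok) < 3.0
    assert abs(z_bad) > abs(z_ok) and p_bad < 0.01


def test_calibration_slope_recovery_and_half_slope():
    rng = np.random.default_rng(8)
    n = 20000
    lp = rng.normal(0, 1.5, size=n)
    q = 1 / (1 + np.exp(-lp))
    y = (rng.uniform(size=n) < q).astype(int)
    slope, intercept, fallback = calibration_slope(q, y)
    assert not fallback
    assert slope == pytest.approx(1.0, abs=0.05)
    assert intercept == pytest.approx(0.0, abs=0.05)
    # doubling the logit halves the recalibration slope
    over = 1 / (1 + np.exp(-2 * lp))
    slope2, _, _ = calibration_slope(over, y)
    assert slope2 == pytest.approx(0.5, abs=0.05)


def test_calibration_slope_rejects_single_class():
    with pytest.raises(DiagnosticsError):
        calibration_slope([0.2, 0.4], [1, 1])


def test_mean_calibration_error_hand_example():
    # two bins: (0.1, 0.1, y = 0,0 -> |0.1-0|), (0.8, 0.8, y = 1,1 -> |0.8-1|)
    probs = [0.1, 0.1, 0.8, 0.8]
    y = [0, 0, 1, 1]
    expected = (0.1 + 0.2) / 2 * 100
    assert mean_calibration_error(probs, y, bins=2) == pytest.approx(expected)


def test_mean_calibration_error_bounds(rng):
    probs = rng.uniform(0.01, 0.99, size=50)
    y = (rng.uniform(size=50) < 0.5).astype(int)
    e = mean_calibration_error(probs, y, bins=5)
    assert 0.0 <= e <= 100.0
    exact = mean_calibration_error(y * 0.98 + 0.01, y, bins=2)
    assert exact < 2.1  # probs nearly equal to event rates


# ------------------------------ paired tests ---------------------------------

def test_pre_post_comparison_trivials(rng):
    pre = rng.normal(size=30)
    assert pre_post_comparison(pre, pre.copy(), "paired_t")[1] == 1.0
    t_pos, p1 = pre_post_comparison(pre, pre + 1.0, "paired_t")
    t_neg, p2 = pre_post_comparison(pre + 1.0, pre, "paired_t")
    assert t_pos == pytest.approx(-t_neg)  # sign-flip antisymmetry
    assert p1 < 0.01 and p1 == pytest.approx(p2)


def test_pre_post_comparison_matches_scipy_directly(rng):
    pre = rng.normal(size=25)
    post = pre + rng.normal(0.5, 1.0, size=25)
    s, p = pre_post_comparison(pre, post, "wilcoxon_signed_rank")
    ref = stats.wilcoxon(post, pre)
    assert (s, p) == (ref.statistic, ref.pvalue)
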