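"""ROC analysis, resampling inference and calibration for small cohorts.

Conventions
-----------
The positive class is the rare, clinically unfavorable one (here: shunt
*nonresponder*); a higher score means "more positive". The pipeline maps
low improvement rates to high nonresponse scores, either through the
Firth-model predicted probability of nonresponse (default) or by sign
flipping the raw rate.

AUC uses the Mann-Whitney form with half credit for ties. The Youden
operating point maximizes J = sensitivity + specificity - 1 over all
midpoints between adjacent observed scores (ties broken toward the
smallest threshold). Confidence intervals are stratified percentile
bootstrap; permutation p-values use the penalized likelihood-ratio
statistic of the covariate block of interest; calibration is summarized by
the Spiegelhalter z-test, a logistic recalibration slope/intercept, and a
binned mean absolute calibration error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .firth import FirthError, FirthFit, fit_firth, penalized_lr_stat

__all__ = [
    "DiagnosticsError",
    "ResamplingConfig",
    "RocCurve",
    "auc",
    "roc_curve",
    "youden_cutoff",
    "confusion_metrics",
    "metrics_from_rates",
    "delong_variance",
    "delong_test",
    "stratified_bootstrap_ci",
    "permutation_pvalue",
    "spiegelhalter_test",
    "calibration_slope",
    "mean_calibration_error",
    "pre_post_comparison",
]


class DiagnosticsError(ValueError):
    pass


@dataclass(frozen=True)
class ResamplingConfig:
    """Sizes and seed for bootstrap/permutation inference."""

    bootstrap_B: int = 2000
    permutation_B: int = 5000
    stratified: bool = True
    seed: int = 0
    level: float = 0.95

    def __post_init__(self):
        if self.bootstrap_B < 1 or self.permutation_B < 1:
            raise DiagnosticsError("resample counts must be >= 1")


@dataclass
class RocCurve:
    """Thresholds (with +-inf sentinels) and the operating points they induce."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    positive_class: str = "nonresponder"


def _validate_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise DiagnosticsError("scores and labels must have equal length")
    if not np.all((labels == 0) | (labels == 1)):
        raise DiagnosticsError("labels must be binary 0/1")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise DiagnosticsError("both classes must be present")
    return scores, labels


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(s+ > s-) + 1/2 P(s+ = s-), computed via ranks."""
    scores, labels = _validate_scores(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(scores)  # midranks handle ties exactly
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def roc_curve(scores, labels, positive_class: str = "nonresponder") -> RocCurve:
    """Empirical ROC over thresholds "call positive iff score >= t"."""
    scores, labels = _validate_scores(scores, labels)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], uniq, mids, [np.inf]))
    thresholds.sort()
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    sens = np.array([(scores[labels == 1] >= t).sum() / n_pos for t in thresholds])
    spec = np.array([(scores[labels == 0] < t).sum() / n_neg for t in thresholds])
    return RocCurve(thresholds, sens, spec, positive_class)


def youden_cutoff(scores, labels) -> tuple[float, float]:
    """(cutoff, J) maximizing J = sens + spec - 1.

    The cutoff is reported as the midpoint between the adjacent observed
    scores; ties go to the smallest qualifying threshold. A degenerate
    score vector (all equal) yields J = 0.
    """
    scores, labels = _validate_scores(scores, labels)
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0]), 0.0
    # candidate thresholds: midpoints between adjacent unique scores,
    # plus one below the minimum and one above the maximum
    gap = uniq[1] - uniq[0] if len(uniq) > 1 else 1.0
    cands = np.concatenate(([uniq[0] - gap / 2.0],
                            (uniq[:-1] + uniq[1:]) / 2.0,
                            [uniq[-1] + (uniq[-1] - uniq[-2]) / 2.0]))
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_c, best_j = cands[0], -np.inf
    for c in cands:
        sens = (scores[labels == 1] >= c).sum() / n_pos
        spec = (scores[labels == 0] < c).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-15:
            best_c, best_j = c, j
    return float(best_c), float(best_j)


def confusion_metrics(scores, labels, cutoff: float) -> dict:
    """Confusion counts and sens/spec/PPV/NPV at "positive iff score >= cutoff"."""
    scores, labels = _validate_scores(scores, labels)
    if not math.isfinite(cutoff):
        raise DiagnosticsError("cutoff must be finite")
    calls = scores >= cutoff
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    fn = int(np.sum(~calls & (labels == 1)))
    tn = int(np.sum(~calls & (labels == 0)))
    flags = set()
    if tp + fp == 0:
        flags.add("ppv_undefined")
    if tn + fn == 0:
        flags.add("npv_undefined")
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if tp + fp else None,
        "npv": tn / (tn + fn) if tn + fn else None,
        "flags": flags,
    }


def metrics_from_rates(sens: float, spec: float, n_pos: int, n_neg: int,
                       decimals: int = 3) -> dict:
    """Recover the unique integer confusion matrix behind rounded rates.

    Given sensitivity and specificity printed to ``decimals`` places and
    the class sizes, find the (tp, fn, tn, fp) whose exact rates round
    (half-up) back to the inputs; derive PPV/NPV from it. Raises if no or
    several matrices are consistent.
    """
    from decimal import Decimal, ROUND_HALF_UP

    def round_half_up(x: float) -> Decimal:
        return Decimal(repr(x)).quantize(Decimal(1).scaleb(-decimals),
                                         rounding=ROUND_HALF_UP)

    target_sens, target_spec = round_half_up(sens), round_half_up(spec)
    tps = [tp for tp in range(n_pos + 1)
           if round_half_up(tp / n_pos) == target_sens]
    tns = [tn for tn in range(n_neg + 1)
           if round_half_up(tn / n_neg) == target_spec]
    if len(tps) != 1 or len(tns) != 1:
        raise DiagnosticsError(
            f"no unique confusion matrix: tp candidates {tps}, tn candidates {tns}")
    tp, tn = tps[0], tns[0]
    fn, fp = n_pos - tp, n_neg - tn
    return {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "sensitivity": tp / n_pos, "specificity": tn / n_neg,
        "ppv": tp / (tp + fp) if tp + fp else None,
        "npv": tn / (tn + fn) if tn + fn else None,
    }


# --------------------------------------------------------------------------
# DeLong machinery
# --------------------------------------------------------------------------

def _placements(scores, labels):
    """Per-observation structural components (V10 for positives, V01 for
    negatives) of the Mann-Whitney AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    cmp_mat = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    return cmp_mat.mean(axis=1), cmp_mat.mean(axis=0), cmp_mat.mean()


def delong_variance(scores, labels) -> float:
    """Variance of a single empirical AUC from its structural components."""
    scores, labels = _validate_scores(scores, labels)
    v10, v01, _ = _placements(scores, labels)
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired comparison of two correlated AUCs; returns (Z, two-sided p)."""
    scores_a, labels = _validate_scores(scores_a, labels)
    scores_b, _ = _validate_scores(scores_b, labels)
    va10, va01, auc_a = _placements(scores_a, labels)
    vb10, vb01, auc_b = _placements(scores_b, labels)
    m, n = len(va10), len(va01)
    var_a = (va10.var(ddof=1) / m if m > 1 else 0.0) \
        + (va01.var(ddof=1) / n if n > 1 else 0.0)
    var_b = (vb10.var(ddof=1) / m if m > 1 else 0.0) \
        + (vb01.var(ddof=1) / n if n > 1 else 0.0)
    cov = 0.0
    if m > 1:
        cov += float(np.cov(va10, vb10, ddof=1)[0, 1]) / m
    if n > 1:
        cov += float(np.cov(va01, vb01, ddof=1)[0, 1]) / n
    denom = var_a + var_b - 2.0 * cov
    if denom <= 0:
        return 0.0, 1.0
    z = float((auc_a - auc_b) / math.sqrt(denom))
    return z, float(2.0 * stats.norm.sf(abs(z)))


# --------------------------------------------------------------------------
# Resampling
# --------------------------------------------------------------------------

def stratified_bootstrap_ci(statistic: Callable[[np.ndarray], float],
                            labels, config: ResamplingConfig,
                            rng: Optional[np.random.Generator] = None
                            ) -> tuple[float, float, int]:
    """Percentile bootstrap CI of ``statistic(indices)``.

    Resampling is with replacement within each outcome class (so a
    cohort with 5 positives never loses the positive class). The
    statistic receives the resampled index vector; resamples on which it
    raises or returns NaN are dropped and counted.

    Returns (low, high, n_failed).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    labels = np.asarray(labels, dtype=int)
    if config.stratified:
        strata = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    else:
        strata = [np.arange(len(labels))]
    values, failed = [], 0
    for _ in range(config.bootstrap_B):
        idx = np.concatenate([rng.choice(s, size=len(s), replace=True)
                              for s in strata])
        try:
            v = statistic(idx)
        except (DiagnosticsError, FirthError, ValueError):
            failed += 1
            continue
        if v is None or not math.isfinite(v):
            failed += 1
            continue
        values.append(v)
    if not values:
        raise DiagnosticsError("all bootstrap resamples failed")
    alpha = 1.0 - config.level
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi), failed


def permutation_pvalue(X_full, X_null, y, config: ResamplingConfig,
                       rng: Optional[np.random.Generator] = None,
                       full_names: Optional[Sequence[str]] = None,
                       null_names: Optional[Sequence[str]] = None
                       ) -> tuple[float, float, int]:
    """Permutation p-value for the covariate block X_full \\ X_null.

    The outcome is permuted ``permutation_B`` times; each time both Firth
    models are refit and the penalized likelihood-ratio statistic
    recorded. Non-convergent refits are counted as at least as extreme as
    the observed statistic (conservative). p = (#{perm >= obs} + 1)/(B + 1).

    Returns (p, observed statistic, n_nonconverged).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    X_full = np.asarray(X_full, dtype=float)
    X_null = np.asarray(X_null, dtype=float)
    y = np.asarray(y, dtype=int)
    full_names = tuple(full_names) if full_names else tuple(
        f"x{j}" for j in range(X_full.shape[1]))
    null_names = tuple(null_names) if null_names else full_names[:X_null.shape[1]]

    fit_full = fit_firth(X_full, y, column_names=full_names)
    fit_null = fit_firth(X_null, y, column_names=null_names)
    observed = penalized_lr_stat(fit_full, fit_null)

    # an intercept-only null depends on y only through sum(y): fit it once
    null_is_constant = X_null.shape[1] == 1 and np.ptp(X_null[:, 0]) == 0
    exceed, bad = 0, 0
    for _ in range(config.permutation_B):
        yp = rng.permutation(y)
        try:
            f_full = fit_firth(X_full, yp, column_names=full_names)
            f_null = fit_null if null_is_constant else fit_firth(
                X_null, yp, column_names=null_names)
            if not (f_full.converged and f_null.converged):
                raise FirthError("non-convergence")
            stat = penalized_lr_stat(f_full, f_null)
        except FirthError:
            bad += 1
            exceed += 1
            continue
        if stat >= observed:
            exceed += 1
    p = (exceed + 1) / (config.permutation_B + 1)
    return float(p), float(observed), bad


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

def spiegelhalter_test(probs, outcomes) -> tuple[float, float]:
    """Spiegelhalter z-test of overall calibration; returns (z, two-sided p)."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise DiagnosticsError("probabilities must lie strictly in (0,1)")
    num = float(np.sum((y - p) * (1.0 - 2.0 * p)))
    den = float(np.sum((1.0 - 2.0 * p) ** 2 * p * (1.0 - p)))
    if den == 0.0:
        return 0.0, 1.0
    z = num / math.sqrt(den)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def calibration_slope(probs, outcomes, max_iter: int = 100
                      ) -> tuple[float, float, bool]:
    """Logistic recalibration of outcomes on logit(probs).

    Returns (slope, intercept, firth_fallback). Slope 1 / intercept 0 is
    perfect calibration; slope > 1 indicates overconfidence was *under*-
    spread, < 1 overconfidence. Plain ML Newton is used; separation or
    non-convergence falls back to the Firth fit (flagged).
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise DiagnosticsError("probabilities must lie strictly in (0,1)")
    if y.sum() == 0 or y.sum() == len(y):
        raise DiagnosticsError("both outcome classes required for recalibration")
    lp = np.log(p / (1.0 - p))
    X = np.column_stack([np.ones_like(lp), lp])
    beta = np.zeros(2)
    ok = False
    for _ in range(max_iter):
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = pi * (1.0 - pi)
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, X.T @ (y - pi))
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            ok = True
            break
    if ok and np.max(np.abs(beta)) < 50:
        return float(beta[1]), float(beta[0]), False
    fit = fit_firth(X, y.astype(int), column_names=("intercept", "logit_p"))
    return float(fit.coefficients[1]), float(fit.coefficients[0]), True


def mean_calibration_error(probs, outcomes, bins: int = 10) -> float:
    """Average over equal-count bins of |mean prob - event rate|, in percent.

    Bins with fewer than one observation are merged with their neighbor.
    """
    if bins < 2:
        raise DiagnosticsError("bins >= 2")
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    order = np.argsort(p, kind="stable")
    splits = np.array_split(order, bins)
    splits = [s for s in splits if len(s)]  # empty bins merge by dropping
    errs = [abs(p[s].mean() - y[s].mean()) for s in splits]
    return float(np.mean(errs) * 100.0)


def pre_post_comparison(pre, post, kind: str = "wilcoxon_signed_rank"
                        ) -> tuple[float, float]:
    """Two-sided paired comparison; (statistic, p).

    ``kind`` is ``paired_t`` or ``wilcoxon_signed_rank``. Zero-variance
    differences give p = 1 by convention.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise DiagnosticsError("need paired vectors of length >= 2")
    diff = post - pre
    if np.allclose(diff, diff[0]) and diff[0] == 0:
        return 0.0, 1.0
    if kind == "paired_t":
        res = stats.ttest_rel(post, pre)
    elif kind == "wilcoxon_signed_rank":
        nonzero = diff[diff != 0]
        if nonzero.size < 2:
            return 0.0, 1.0
        res = stats.wilcoxon(post, pre)
    else:
        raise DiagnosticsError(f"unknown comparison kind {kind!r}")
    return float(res.statistic), float(res.pvalue)
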