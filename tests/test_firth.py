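"""Penalized logistic regression against closed-form and ML oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from inpheld.firth import (
    FirthError,
    fit_firth,
    penalized_lr_stat,
    predict_prob,
    profile_interval,
    wald_interval,
)


def expand_2x2(a, b, c, d):
    """Individual-level data for cell counts (y=1,x=1)=a, (y=0,x=1)=b,
    (y=1,x=0)=c, (y=0,x=0)=d."""
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return np.column_stack([np.ones_like(x), x]), y


def haldane_or(a, b, c, d):
    """Closed-form penalized OR of the saturated 2x2 model: the Jeffreys
    penalty is equivalent to adding 1/2 to every cell."""
    return (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))


def test_2x2_closed_form_example():
    X, y = expand_2x2(2, 1, 1, 2)
    fit = fit_firth(X, y)
    assert fit.converged
    assert fit.odds_ratios[1] == pytest.approx(25 / 9, rel=1e-8)


@settings(max_examples=60)
@given(st.tuples(*[st.integers(0, 6)] * 4))
def test_2x2_closed_form_property(cells):
    a, b, c, d = cells
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        return  # outcome or covariate degenerate
    X, y = expand_2x2(a, b, c, d)
    fit = fit_firth(X, y)
    assert fit.converged
    assert fit.odds_ratios[1] == pytest.approx(haldane_or(a, b, c, d), rel=1e-6)


def test_predicted_probs_match_half_corrected_cell_proportions():
    a, b, c, d = 3, 2, 1, 4
    X, y = expand_2x2(a, b, c, d)
    fit = fit_firth(X, y)
    p = predict_prob(fit, np.array([[1.0, 1.0], [1.0, 0.0]]))
    assert p[0] == pytest.approx((a + 0.5) / (a + b + 1), rel=1e-6)
    assert p[1] == pytest.approx((c + 0.5) / (c + d + 1), rel=1e-6)
    assert np.all((p > 0) & (p < 1))


def test_finite_and_converged_under_complete_separation():
    x = np.r_[-4.0, -3.0, -2.0, -1.0, 1.0, 2.0, 3.0, 4.0]
    y = (x > 0).astype(float)
    fit = fit_firth(np.column_stack([np.ones(8), x]), y)
    assert fit.converged
    assert np.all(np.isfinite(fit.coefficients))
    assert np.all(np.isfinite(fit.standard_errors))


def test_bias_correction_approaches_ml_with_growing_n():
    """Firth and ML estimates agree to O(1/n); the gap must shrink."""
    import statsmodels.api as sm

    beta = np.array([-0.5, 0.8])
    gaps = []
    for n in (50, 500, 5000):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
        ml = sm.Logit(y, X).fit(disp=0)
        fit = fit_firth(X, y)
        gaps.append(np.abs(fit.coefficients - ml.params).max())
    assert gaps[2] < gaps[0]
    assert gaps[2] < 0.02


def test_hat_values_sum_to_design_rank(rng):
    n = 80
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    y = (rng.uniform(size=n) < 0.4).astype(float)
    fit = fit_firth(X, y)
    assert fit.hat_values.sum() == pytest.approx(3.0, abs=1e-6)
    assert np.all((fit.hat_values >= 0) & (fit.hat_values <= 1))


def test_rank_deficient_design_names_columns(rng):
    n = 30
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x, 2 * x])
    y = (rng.uniform(size=n) < 0.5).astype(float)
    with pytest.raises(FirthError, match="rank deficient"):
        fit_firth(X, y, column_names=("intercept", "x", "x2"))


def test_single_class_outcome_rejected():
    X = np.column_stack([np.ones(5), np.arange(5.0)])
    with pytest.raises(FirthError, match="event"):
        fit_firth(X, np.ones(5))


@pytest.fixture(scope="module")
def fit_and_data():
    rng = np.random.default_rng(3)
    n = 400
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(-0.3 + 0.7 * x)))).astype(float)
    return fit_firth(X, y), X, y


class TestIntervals:
    def test_wald_interval_monotone_in_level(self, fit_and_data):
        fit, _, _ = fit_and_data
        lo95, hi95 = wald_interval(fit, 0.95)
        lo99, hi99 = wald_interval(fit, 0.99)
        assert np.all(lo99 < lo95) and np.all(hi99 > hi95)
        assert np.all(lo95 < fit.odds_ratios) and np.all(fit.odds_ratios < hi95)

    def test_wald_brackets_2x2_closed_form(self):
        X, y = expand_2x2(2, 1, 1, 2)
        fit = fit_firth(X, y)
        lo, hi = wald_interval(fit)
        assert lo[1] < 25 / 9 < hi[1]

    def test_profile_close_to_wald_for_well_conditioned_data(self, fit_and_data):
        fit, X, y = fit_and_data
        lo_w, hi_w = wald_interval(fit)
        lo_p, hi_p = profile_interval(fit, X, y, j=1)
        assert lo_p == pytest.approx(lo_w[1], rel=0.05)
        assert hi_p == pytest.approx(hi_w[1], rel=0.05)

    def test_profile_finite_on_separated_data(self):
        x = np.r_[-3.0, -2.0, -1.0, 1.0, 2.0, 3.0]
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(6), x])
        fit = fit_firth(X, y)
        lo, hi = profile_interval(fit, X, y, j=1)
        assert 0 < lo < hi < np.inf


class TestPenalizedLR:
    def test_full_equals_null_gives_zero(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.uniform(size=n) < 0.5).astype(float)
        fit = fit_firth(X, y, column_names=("intercept", "x"))
        assert penalized_lr_stat(fit, fit) == 0.0

    def test_noise_covariate_gives_small_nonnegative_stat(self, rng):
        n = 100
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.uniform(size=n) < 0.4).astype(float)
        full = fit_firth(X, y, column_names=("intercept", "x"))
        null = fit_firth(X[:, :1], y, column_names=("intercept",))
        stat = penalized_lr_stat(full, null)
        assert 0.0 <= stat < 15.0

    def test_non_nested_designs_rejected(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        full = fit_firth(X, (rng.uniform(size=n) < 0.5).astype(float),
                         column_names=("intercept", "a"))
        other = fit_firth(X, (rng.uniform(size=n) < 0.5).astype(float),
                          column_names=("intercept", "b"))
        with pytest.raises(FirthError, match="nested"):
            penalized_lr_stat(full, other)

    def test_power_against_strong_effect(self):
        """A log-OR of log(5) at n=200 should clear the chi2 95th percentile
        in most replicates."""
        crit = stats.chi2.ppf(0.95, 1)
        hits = 0
        reps = 40
        for k in range(reps):
            rng = np.random.default_rng(1000 + k)
            x = (rng.uniform(size=200) < 0.5).astype(float)
            eta = -1.0 + np.log(5.0) * x
            y = (rng.uniform(size=200) < 1 / (1 + np.exp(-eta))).astype(float)
            X = np.column_stack([np.ones(200), x])
            full = fit_firth(X, y, column_names=("intercept", "x"))
            null = fit_firth(X[:, :1], y, column_names=("intercept",))
            if penalized_lr_stat(full, null) > crit:
                hits += 1
        assert hits / reps > 0.8
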