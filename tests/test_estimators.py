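"""Estimator correctness against closed forms and a generic WLS oracle."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from mrkit.errors import AnalysisError
from mrkit.estimators import (egger, ivw, or_with_ci, ratio_estimates,
                              weighted_median, weighted_median_from_arrays)

from conftest import make_harmonized


def test_ratio_estimate_closed_form():
    data = make_harmonized([0.1], [0.01], [0.05], [0.02])
    (r,) = ratio_estimates(data)
    assert r.estimate == pytest.approx(0.5)
    assert r.se == pytest.approx(0.2)
    assert r.weight == pytest.approx(r.se ** -2, rel=1e-12)


def test_ratio_estimate_zero_outcome():
    data = make_harmonized([0.1], [0.01], [0.0], [0.02])
    (r,) = ratio_estimates(data)
    assert r.estimate == 0.0
    assert r.se == pytest.approx(0.2)


def test_ratio_estimate_matches_independent_arithmetic(rng):
    k = 25
    bx = rng.normal(0.05, 0.02, k)
    bx[np.abs(bx) < 1e-3] = 0.01
    by = rng.normal(0, 0.01, k)
    sy = rng.uniform(0.001, 0.01, k)
    data = make_harmonized(bx, np.full(k, 0.002), by, sy)
    for j, r in enumerate(ratio_estimates(data)):
        assert r.estimate == pytest.approx(by[j] / bx[j], rel=1e-12)
        assert r.se == pytest.approx(sy[j] / abs(bx[j]), rel=1e-12)


def test_ratio_zero_exposure_names_variant():
    data = make_harmonized([0.0], [0.01], [0.05], [0.02])
    with pytest.raises(AnalysisError, match="rs0"):
        ratio_estimates(data)


def test_ivw_single_pair_degenerates_to_ratio():
    data = make_harmonized([0.1], [0.01], [0.05], [0.02])
    est, het = ivw(data, model="fixed")
    assert est.theta == pytest.approx(0.5)
    assert het is None


def test_ivw_symmetric_average_with_equal_weights():
    # equal |bx| and sy => equal weights; ratios 0.2 and 0.4
    data = make_harmonized([0.1, 0.1], [0.01, 0.01], [0.02, 0.04],
                           [0.02, 0.02])
    est, het = ivw(data, model="fixed")
    assert est.theta == pytest.approx(0.3)
    w = (0.1 / 0.02) ** 2
    assert het.Q == pytest.approx(w * 0.02)
    assert het.df == 1


def test_ivw_matches_wls_oracle(random_harmonized):
    """Origin-WLS normal equations (statsmodels) reproduce IVW to 1e-10."""
    data = random_harmonized
    bx = np.array([p.beta_exposure for p in data.pairs])
    by = np.array([p.beta_outcome for p in data.pairs])
    sy = np.array([p.se_outcome for p in data.pairs])
    fit = sm.WLS(by, bx, weights=sy ** -2).fit()
    est_fe, het = ivw(data, model="fixed")
    est_mre, _ = ivw(data, model="multiplicative_random")
    k = len(data.pairs)
    assert est_fe.theta == pytest.approx(fit.params[0], abs=1e-10)
    # statsmodels scales the variance by RSS_w/(k-1); remove that factor
    # to recover the fixed-effects SE, keep it for the multiplicative one.
    scale = math.sqrt(fit.scale)
    assert est_fe.se == pytest.approx(fit.bse[0] / scale, abs=1e-10)
    if scale >= 1:
        assert est_mre.se == pytest.approx(fit.bse[0], abs=1e-10)
    assert het.Q == pytest.approx(fit.scale * (k - 1), rel=1e-10)


def test_ivw_mre_se_never_below_fe(rng):
    for seed in range(20):
        local = np.random.default_rng(seed)
        k = 10
        bx = local.normal(0.05, 0.01, k)
        by = local.normal(0.5 * bx, 0.01)
        data = make_harmonized(bx, np.full(k, 0.002), by, np.full(k, 0.01))
        fe, het = ivw(data, model="fixed")
        mre, _ = ivw(data, model="multiplicative_random")
        assert mre.se >= fe.se
        if het.Q <= k - 1:
            assert mre.se == pytest.approx(fe.se)


def test_ivw_invariant_to_sign_flips_and_reordering(random_harmonized):
    import dataclasses
    base, _ = ivw(random_harmonized, model="fixed")
    flipped_pairs = [dataclasses.replace(p, beta_exposure=-p.beta_exposure,
                                         beta_outcome=-p.beta_outcome)
                     for p in random_harmonized.pairs]
    reordered = list(reversed(flipped_pairs))
    data2 = make_harmonized(
        [p.beta_exposure for p in reordered],
        [p.se_exposure for p in reordered],
        [p.beta_outcome for p in reordered],
        [p.se_outcome for p in reordered])
    alt, _ = ivw(data2, model="fixed")
    assert alt.theta == pytest.approx(base.theta, abs=1e-14)


def test_egger_recovers_exact_line():
    """Data exactly on beta_y = a + theta*beta_x is interpolated exactly."""
    bx = np.array([0.02, 0.04, 0.06, 0.08, 0.1])
    a, theta = 0.003, 0.7
    by = a + theta * bx
    data = make_harmonized(bx, np.full(5, 0.002), by, np.full(5, 0.004))
    est, het = egger(data)
    assert est.theta == pytest.approx(theta, abs=1e-10)
    assert het.egger_intercept == pytest.approx(a, abs=1e-10)


def test_egger_matches_wls_oracle(random_harmonized):
    data = random_harmonized
    bx = np.array([p.beta_exposure for p in data.pairs])
    by = np.array([p.beta_outcome for p in data.pairs])
    sy = np.array([p.se_outcome for p in data.pairs])
    sign = np.where(bx < 0, -1.0, 1.0)
    X = sm.add_constant(bx * sign)
    fit = sm.WLS(by * sign, X, weights=sy ** -2).fit()
    est, het = egger(data)
    assert est.theta == pytest.approx(fit.params[1], abs=1e-10)
    assert het.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
    if fit.scale >= 1:  # our SE scaling is floored at 1
        assert est.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert het.egger_intercept_se == pytest.approx(fit.bse[0], abs=1e-10)
        assert est.pvalue == pytest.approx(fit.pvalues[1], rel=1e-8)


def test_egger_slope_equals_ivw_when_intercept_zero():
    bx = np.array([0.02, 0.04, 0.06, 0.08])
    theta = 0.5
    by = theta * bx  # exact line through the origin
    data = make_harmonized(bx, np.full(4, 0.002), by, np.full(4, 0.004))
    e, het = egger(data)
    i, _ = ivw(data, model="fixed")
    assert het.egger_intercept == pytest.approx(0, abs=1e-12)
    assert e.theta == pytest.approx(i.theta, abs=1e-10)


def test_egger_requires_three_pairs():
    data = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
    with pytest.raises(AnalysisError):
        egger(data)


def test_weighted_median_simple_median():
    # equal weights, ratios 0.1 / 0.3 / 0.9
    data = make_harmonized([0.1, 0.1, 0.1], [0.01] * 3, [0.01, 0.03, 0.09],
                           [0.02] * 3)
    est = weighted_median(data, n_boot=200, seed=7)
    assert est.theta == pytest.approx(0.3)


def test_weighted_median_equal_weights_odd_k_is_sample_median(rng):
    for _ in range(20):
        k = 2 * int(rng.integers(1, 8)) + 1
        ratios = rng.normal(0, 1, k)
        w = np.full(k, 3.7)
        assert weighted_median_from_arrays(ratios, w) == pytest.approx(
            float(np.median(ratios)), abs=1e-12)


def test_weighted_median_dominant_weight():
    # middle pair holds >50% of total weight: estimate stays within the
    # interpolation neighborhood of its ratio
    ratios = np.array([0.1, 0.5, 0.9])
    weights = np.array([1.0, 10.0, 1.0])
    est = weighted_median_from_arrays(ratios, weights)
    assert 0.4 < est < 0.6


def test_weighted_median_bootstrap_is_seeded(random_harmonized):
    a = weighted_median(random_harmonized, n_boot=200, seed=3)
    b = weighted_median(random_harmonized, n_boot=200, seed=3)
    c = weighted_median(random_harmonized, n_boot=200, seed=4)
    assert a.se == b.se
    assert a.se != c.se


def test_or_with_ci_null_effect():
    orr, lo, hi = or_with_ci(0.0, 0.1)
    assert orr == 1.0
    assert lo == pytest.approx(math.exp(-1.96 * 0.1))
    assert hi == pytest.approx(math.exp(1.96 * 0.1))


def test_or_with_ci_reconstructs_printed_interval():
    """OR 2.989 with CI 1.521-5.874: SE recovered by inverting the width."""
    theta = math.log(2.989)
    se = (math.log(5.874) - math.log(1.521)) / (2 * 1.96)
    orr, lo, hi = or_with_ci(theta, se)
    assert round(orr, 3) == 2.989
    assert round(lo, 3) == 1.521
    assert round(hi, 3) == 5.874


def test_or_with_ci_log_inverse(rng):
    for _ in range(25):
        theta = rng.normal(0, 1)
        se = rng.uniform(0.01, 1)
        orr, lo, hi = or_with_ci(theta, se)
        assert math.log(orr) == pytest.approx(theta, abs=1e-12)
        assert math.log(hi / lo) == pytest.approx(2 * 1.96 * se, abs=1e-10)
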