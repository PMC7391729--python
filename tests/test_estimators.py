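import math

import numpy as np
import pytest
from scipy import stats as sps

from bidimr.estimators import (
    Z95,
    EstimationError,
    NotFeasible,
    ci_and_p,
    cochran_q,
    egger,
    ivw,
    median_estimate,
    wald_ratio,
)
from bidimr.harmonize import STATUS_ALIGNED, HarmonizedPair

from conftest import make_pairs, random_pairs


def _pair(bx=0.5, sx=0.02, by=0.1, sy=0.05, rsid="rs1"):
    return HarmonizedPair(rsid, bx, sx, by, sy, STATUS_ALIGNED)


class TestCiAndP:
    def test_null_center(self):
        lo, hi, p = ci_and_p(0.0, 0.3)
        assert p == pytest.approx(1.0)
        assert lo == pytest.approx(-hi)

    def test_invariant_exact_multiplier(self):
        lo, hi, _ = ci_and_p(1.234, 0.567)
        assert lo == pytest.approx(1.234 - 1.959964 * 0.567, abs=1e-12)
        assert hi == pytest.approx(1.234 + 1.959964 * 0.567, abs=1e-12)

    def test_pvalue_is_two_sided_normal(self):
        _, _, p = ci_and_p(0.2, 0.1)
        assert p == pytest.approx(2 * sps.norm.sf(2.0), rel=1e-12)

    def test_se_domain_error(self):
        with pytest.raises(EstimationError):
            ci_and_p(0.1, 0.0)

    def test_printed_interval_bounds(self):
        # printed-abstract conventions: (-0.16, 0.03) -> (-0.22, -0.10)
        lo, hi, _ = ci_and_p(-0.16, 0.03)
        assert round(lo, 2) == -0.22
        assert round(hi, 2) == -0.10
        lo, _, _ = ci_and_p(-0.26, 0.06)
        assert round(lo, 2) == -0.38


class TestWaldRatio:
    def test_first_order_arithmetic(self):
        est = wald_ratio(_pair(bx=0.5, by=0.1, sy=0.05), order=1)
        assert est.estimate == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)
        assert est.n_snps == 1

    def test_zero_outcome_effect(self):
        est = wald_ratio(_pair(by=0.0))
        assert est.estimate == 0.0
        assert est.pvalue == pytest.approx(1.0)

    def test_zero_bx_domain_error(self):
        with pytest.raises(EstimationError, match="no exposure effect"):
            wald_ratio(_pair(bx=0.0))

    def test_second_order_formula(self):
        p = _pair(bx=0.5, sx=0.02, by=0.1, sy=0.05)
        est = wald_ratio(p, order=2)
        expected = math.sqrt(0.05**2 / 0.5**2 + 0.1**2 * 0.02**2 / 0.5**4)
        assert est.se == pytest.approx(expected, rel=1e-12)

    def test_second_order_against_monte_carlo(self, rng):
        # oracle: empirical SD of by*/bx* over 1e6 draws
        bx, sx, by, sy = 0.5, 0.02, 0.1, 0.05
        n = 1_000_000
        bx_star = rng.normal(bx, sx, n)
        by_star = rng.normal(by, sy, n)
        mc_sd = np.std(by_star / bx_star)
        est = wald_ratio(_pair(bx=bx, sx=sx, by=by, sy=sy), order=2)
        assert est.se == pytest.approx(mc_sd, rel=0.02)


class TestIvw:
    def test_single_pair_reduces_to_wald(self):
        p = _pair()
        est_ivw = ivw([p])
        est_wald = wald_ratio(p, order=1)
        assert est_ivw.estimate == pytest.approx(est_wald.estimate, rel=1e-14)
        assert est_ivw.se == pytest.approx(est_wald.se, rel=1e-14)

    def test_duplicated_pair_shrinks_se_by_sqrt2(self):
        p1, p2 = _pair(rsid="rs1"), _pair(rsid="rs2")
        one = ivw([p1])
        two = ivw([p1, p2])
        assert two.estimate == pytest.approx(one.estimate)
        assert two.se == pytest.approx(one.se / math.sqrt(2), rel=1e-12)

    def test_matches_wls_through_origin(self, rng):
        # oracle: closed-form weighted least squares of by on bx, no intercept
        for _ in range(50):
            pairs = random_pairs(rng, rng.integers(2, 25))
            est = ivw(pairs)
            bx = np.array([p.bx for p in pairs])
            by = np.array([p.by for p in pairs])
            sy = np.array([p.sy for p in pairs])
            w = 1.0 / sy**2
            slope = np.sum(w * bx * by) / np.sum(w * bx**2)
            se = 1.0 / math.sqrt(np.sum(w * bx**2))
            assert est.estimate == pytest.approx(slope, rel=1e-10)
            assert est.se == pytest.approx(se, rel=1e-10)

    def test_multiplicative_random_never_shrinks_se(self, rng):
        for _ in range(20):
            pairs = random_pairs(rng, 10)
            fixed = ivw(pairs, mode="fixed")
            mre = ivw(pairs, mode="multiplicative-random")
            assert mre.se >= fixed.se - 1e-15
            assert mre.estimate == pytest.approx(fixed.estimate)

    def test_zero_bx_pair_excluded(self):
        pairs = [_pair(rsid="rs1"), _pair(rsid="rs2", bx=0.0)]
        est = ivw(pairs)
        assert est.n_snps == 1

    def test_empty_raises(self):
        with pytest.raises(EstimationError):
            ivw([])


class TestEgger:
    def test_not_feasible_below_three(self):
        res = egger(make_pairs([0.3, 0.4], [0.1, 0.1]))
        assert isinstance(res, NotFeasible)
        assert res.n_snps == 2

    def test_noiseless_proportional_fit(self):
        bx = np.array([0.2, 0.3, 0.5, 0.7])
        res = egger(make_pairs(bx, 0.3 * bx))
        assert res.slope.estimate == pytest.approx(0.3, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)

    def test_affine_recovery(self):
        bx = np.array([0.2, 0.3, 0.5, 0.7, 0.9])
        res = egger(make_pairs(bx, 0.05 + 0.3 * bx))
        assert res.slope.estimate == pytest.approx(0.3, abs=1e-10)
        assert res.intercept == pytest.approx(0.05, abs=1e-10)

    def test_degrees_of_freedom(self, rng):
        pairs = random_pairs(rng, 7)
        res = egger(pairs)
        assert res.df == 5

    def test_against_statsmodels_wls(self, rng):
        import statsmodels.api as sm

        for _ in range(50):
            pairs = random_pairs(rng, rng.integers(4, 20))
            res = egger(pairs)
            bx = np.array([p.bx for p in pairs])
            by = np.array([p.by for p in pairs])
            sy = np.array([p.sy for p in pairs])
            sign = np.where(bx < 0, -1.0, 1.0)
            x, y = bx * sign, by * sign
            fit = sm.WLS(y, sm.add_constant(x), weights=1.0 / sy**2).fit()
            assert res.intercept == pytest.approx(fit.params[0], rel=1e-8)
            assert res.slope.estimate == pytest.approx(fit.params[1], rel=1e-8)
            assert res.intercept_se == pytest.approx(fit.bse[0], rel=1e-8)
            assert res.slope.se == pytest.approx(fit.bse[1], rel=1e-8)
            assert res.slope.pvalue == pytest.approx(fit.pvalues[1], rel=1e-6)
            assert res.intercept_pvalue == pytest.approx(fit.pvalues[0], rel=1e-6)

    def test_orientation_invariance(self, rng):
        # negating any subset of (bx, by) rows leaves the fit unchanged
        pairs = random_pairs(rng, 8)
        flipped = [
            HarmonizedPair(p.rsid, -p.bx, p.sx, -p.by, p.sy, p.status)
            if i % 2 == 0 else p
            for i, p in enumerate(pairs)
        ]
        a, b = egger(pairs), egger(flipped)
        assert a.slope.estimate == pytest.approx(b.slope.estimate)
        assert a.intercept == pytest.approx(b.intercept)


class TestMedian:
    def test_odd_count_simple_median(self):
        pairs = make_pairs([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        res = median_estimate(pairs, weighted=False, n_boot=100, seed=1)
        assert res.estimate == pytest.approx(0.2)

    def test_equal_weights_match_simple(self, rng):
        for n in (3, 4, 5, 8):
            ratios = rng.normal(0.2, 0.1, n)
            pairs = make_pairs(np.ones(n), ratios, sy=np.full(n, 0.05))
            simple = median_estimate(pairs, weighted=False, n_boot=50, seed=1)
            weighted = median_estimate(pairs, weighted=True, n_boot=50, seed=1)
            assert weighted.estimate == pytest.approx(simple.estimate, rel=1e-12)

    def test_not_feasible_below_three(self):
        res = median_estimate(make_pairs([0.5], [0.1]), seed=1)
        assert isinstance(res, NotFeasible)

    def test_bootstrap_seeded_reproducible(self, rng):
        pairs = random_pairs(rng, 6)
        a = median_estimate(pairs, n_boot=500, seed=42)
        b = median_estimate(pairs, n_boot=500, seed=42)
        assert a.se == b.se

    def test_majority_valid_recovery(self):
        # 60% valid instruments (theta = 0.25), 40% with direct effects:
        # weighted median lands within 3 bootstrap SEs of truth in >= 90%
        theta = 0.25
        hits = 0
        n_datasets = 200
        root = np.random.default_rng(777)
        for _ in range(n_datasets):
            n = 10
            bx = root.uniform(0.1, 0.4, n)
            sy = np.full(n, 0.02)
            direct = np.zeros(n)
            direct[6:] = root.uniform(0.05, 0.15, 4) * root.choice([-1, 1], 4)
            by = theta * bx + direct + root.normal(0, sy)
            pairs = make_pairs(bx, by, sx=np.full(n, 0.005), sy=sy)
            res = median_estimate(pairs, weighted=True, n_boot=200, seed=int(root.integers(2**31)))
            if abs(res.estimate - theta) <= 3 * res.se:
                hits += 1
        assert hits / n_datasets >= 0.90


class TestCochranQ:
    def test_identical_ratios_zero_q(self):
        bx = np.array([0.2, 0.4, 0.8])
        pairs = make_pairs(bx, 0.3 * bx)
        q = cochran_q(pairs, ivw(pairs))
        assert q.q == pytest.approx(0.0, abs=1e-20)
        assert q.pvalue == pytest.approx(1.0)
        assert q.df == 2

    def test_permutation_invariance(self, rng):
        pairs = random_pairs(rng, 9)
        ref = ivw(pairs)
        q1 = cochran_q(pairs, ref)
        q2 = cochran_q(list(reversed(pairs)), ref)
        assert q1.q == pytest.approx(q2.q, rel=1e-12)

    def test_null_calibration_uniform(self):
        # homogeneous pairs with strong instruments: p-values ~ Uniform(0,1)
        root = np.random.default_rng(2024)
        n_reps, n = 2000, 10
        pvals = np.empty(n_reps)
        for i in range(n_reps):
            bx = root.uniform(0.2, 0.6, n)
            sy = root.uniform(0.01, 0.05, n)
            by = 0.2 * bx + root.normal(0, sy)
            pairs = make_pairs(bx, by, sx=np.full(n, 1e-6), sy=sy)
            pvals[i] = cochran_q(pairs, ivw(pairs)).pvalue
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestEquivariance:
    def test_outcome_scale(self, rng):
        pairs = random_pairs(rng, 8)
        c = 3.7
        scaled = [
            HarmonizedPair(p.rsid, p.bx, p.sx, c * p.by, c * p.sy, p.status) for p in pairs
        ]
        for estimator in (ivw, lambda ps: egger(ps).slope):
            a, b = estimator(pairs), estimator(scaled)
            assert b.estimate == pytest.approx(c * a.estimate, rel=1e-10)
            assert b.se == pytest.approx(c * a.se, rel=1e-10)

    def test_exposure_scale(self, rng):
        pairs = random_pairs(rng, 8)
        c = 2.5
        scaled = [
            HarmonizedPair(p.rsid, c * p.bx, c * p.sx, p.by, p.sy, p.status) for p in pairs
        ]
        a, b = ivw(pairs), ivw(scaled)
        assert b.estimate == pytest.approx(a.estimate / c, rel=1e-10)
        assert b.se == pytest.approx(a.se / c, rel=1e-10)

    def test_sign_flip_preserves_pvalues(self, rng):
        pairs = random_pairs(rng, 8)
        negated = [
            HarmonizedPair(p.rsid, p.bx, p.sx, -p.by, p.sy, p.status) for p in pairs
        ]
        a, b = ivw(pairs), ivw(negated)
        assert b.estimate == pytest.approx(-a.estimate, rel=1e-12)
        assert b.pvalue == pytest.approx(a.pvalue, rel=1e-12)
        ea, eb = egger(pairs), egger(negated)
        assert eb.slope.estimate == pytest.approx(-ea.slope.estimate, rel=1e-10)
        assert eb.slope.pvalue == pytest.approx(ea.slope.pvalue, rel=1e-8)

    def test_egger_zero_intercept_oracle_equals_ivw(self, rng):
        # forcing the intercept to zero in the weighted regression recovers IVW
        pairs = random_pairs(rng, 10)
        bx = np.array([p.bx for p in pairs])
        by = np.array([p.by for p in pairs])
        sy = np.array([p.sy for p in pairs])
        sign = np.where(bx < 0, -1, 1)
        x, y, w = bx * sign, by * sign, 1.0 / sy**2
        slope = np.sum(w * x * y) / np.sum(w * x * x)
        assert ivw(pairs).estimate == pytest.approx(slope, rel=1e-12)


def test_z95_matches_normal_quantile():
    assert Z95 == pytest.approx(sps.norm.ppf(0.975), abs=5e-7)
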