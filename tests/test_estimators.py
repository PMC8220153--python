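"""MR estimator correctness against independent oracles and invariants."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from sexmr.estimators import (
    DegenerateInstrumentsError,
    ivw_fixed,
    ivw_random,
    loo_estimates,
    max_likelihood,
    mr_egger,
    mr_presso,
    weighted_median,
)

from conftest import make_harmonized


class TestIVWFixed:
    def test_single_instrument_is_ratio(self):
        h = make_harmonized([0.1], [0.01], [0.05])
        est = ivw_fixed(h)
        assert est.theta == pytest.approx(0.5)
        assert est.k == 1
        assert est.q_ivs is None

    def test_equal_weights_reduce_to_mean(self):
        h = make_harmonized([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        est = ivw_fixed(h)
        assert est.theta == pytest.approx(0.2)
        assert est.var_theta == pytest.approx(1 / 3)

    def test_matches_wls_oracle(self, rng):
        bx = rng.uniform(0.02, 0.1, 4)
        sy = rng.uniform(0.005, 0.02, 4)
        by = 0.3 * bx + rng.normal(0, sy)
        h = make_harmonized(bx, sy, by)
        est = ivw_fixed(h)
        # independent oracle: no-intercept WLS fit
        fit = sm.WLS(by, bx[:, None], weights=sy**-2.0).fit()
        assert est.theta == pytest.approx(float(fit.params[0]), abs=1e-12)
        # Eq.-style variance is the unscaled (X'WX)^-1
        assert est.var_theta == pytest.approx(float(fit.normalized_cov_params[0, 0]))

    def test_all_zero_exposure_rejected(self):
        h = make_harmonized([0.0, 0.0], [0.01, 0.01], [0.01, 0.02])
        with pytest.raises(DegenerateInstrumentsError):
            ivw_fixed(h)

    def test_order_invariance_and_sign_equivariance(self, rng):
        bx = rng.uniform(0.02, 0.1, 8)
        sy = rng.uniform(0.005, 0.02, 8)
        by = 0.3 * bx + rng.normal(0, sy)
        h = make_harmonized(bx, sy, by)
        perm = rng.permutation(8)
        hp = make_harmonized(bx[perm], sy[perm], by[perm])
        hneg = make_harmonized(bx, sy, -by)
        assert ivw_fixed(hp).theta == pytest.approx(ivw_fixed(h).theta)
        assert ivw_fixed(hneg).theta == pytest.approx(-ivw_fixed(h).theta)

    def test_variance_decreases_as_instruments_accumulate(self, rng):
        bx = rng.uniform(0.02, 0.1, 10)
        sy = rng.uniform(0.005, 0.02, 10)
        by = 0.3 * bx
        variances = [
            ivw_fixed(make_harmonized(bx[: k + 1], sy[: k + 1], by[: k + 1])).var_theta
            for k in range(10)
        ]
        assert all(b < a for a, b in zip(variances, variances[1:]))

    def test_parameter_recovery_coverage(self):
        """theta_hat within 2 se of truth in >= 93% of seeds (nominal 95%)."""
        theta = 0.3
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            bx_true = r.uniform(0.03, 0.08, 20) * r.choice([-1, 1], 20)
            sx = np.full(20, 0.004)
            sy = np.full(20, 0.008)
            bx = r.normal(bx_true, sx)
            by = r.normal(theta * bx_true, sy)
            est = ivw_fixed(make_harmonized(bx, sy, by, se_x=sx))
            hits += abs(est.theta - theta) < 2 * est.se
        assert hits / n_seeds >= 0.93


class TestIVWRandom:
    def test_underdispersion_not_inflated(self):
        h = make_harmonized([0.05, 0.06, 0.07], [0.01, 0.01, 0.01],
                            np.array([0.05, 0.06, 0.07]) * 0.3)
        fixed, random = ivw_fixed(h), ivw_random(h)
        assert random.se == pytest.approx(fixed.se)
        assert random.theta == pytest.approx(fixed.theta)

    def test_constructed_q_doubles_se(self):
        # bx = 1, sy = 1, by symmetric around c: theta = c, Q = sum (by-c)^2.
        c = 0.2
        by = np.array([c - 2, c, c + 2])  # Q = 8 = 4*(k-1)
        h = make_harmonized([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], by)
        fixed, random = ivw_fixed(h), ivw_random(h)
        assert fixed.q_ivs == pytest.approx(8.0)
        assert random.se == pytest.approx(2 * fixed.se)

    def test_proportional_instruments_q_zero(self):
        h = make_harmonized([0.05, 0.08], [0.01, 0.01], [0.015, 0.024])
        est = ivw_random(h)
        assert est.q_ivs == pytest.approx(0.0, abs=1e-25)
        assert est.se == pytest.approx(ivw_fixed(h).se)

    def test_requires_two_instruments(self):
        with pytest.raises(ValueError):
            ivw_random(make_harmonized([0.1], [0.01], [0.05]))


class TestWeightedMedian:
    def test_constant_ratios(self):
        bx = np.array([0.05, 0.08, 0.03])
        h = make_harmonized(bx, [0.01, 0.02, 0.01], 0.4 * bx)
        assert weighted_median(h).theta == pytest.approx(0.4)

    def test_equal_weight_median(self):
        h = make_harmonized([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 2.0, 9.0])
        assert weighted_median(h).theta == pytest.approx(2.0)

    def test_matches_grid_scan_oracle(self):
        bx = np.array([0.05, 0.02, 0.08, 0.04, 0.06])
        sy = np.array([0.01, 0.02, 0.008, 0.015, 0.012])
        by = np.array([0.020, 0.011, 0.030, 0.009, 0.031])
        h = make_harmonized(bx, sy, by)
        theta = weighted_median(h).theta
        # oracle: scan the piecewise-linear cumulative weight function on a grid
        ratios = by / bx
        w = (bx / sy) ** 2
        order = np.argsort(ratios)
        r, ww = ratios[order], w[order]
        s = (np.cumsum(ww) - ww / 2) / ww.sum()
        grid = np.linspace(r[0], r[-1], 200001)
        cum = np.interp(grid, r, s)
        oracle = grid[np.argmin(np.abs(cum - 0.5))]
        assert theta == pytest.approx(oracle, abs=1e-4)

    def test_zero_exposure_effect_named(self):
        h = make_harmonized([0.05, 0.0, 0.08], [0.01, 0.01, 0.01], [0.02, 0.01, 0.03],
                            snps=["rsA", "rsB", "rsC"])
        with pytest.raises(DegenerateInstrumentsError, match="rsB"):
            weighted_median(h)

    def test_bootstrap_se_is_seeded(self):
        h = make_harmonized([0.05, 0.02, 0.08, 0.04], [0.01, 0.02, 0.008, 0.015],
                            [0.020, 0.011, 0.030, 0.009])
        a = weighted_median(h, seed=7)
        b = weighted_median(h, seed=7)
        assert a.se == b.se


class TestMaxLikelihood:
    def test_vanishing_exposure_error_equals_ivw(self):
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.03, 0.09, 10)
        sy = rng.uniform(0.005, 0.02, 10)
        by = 0.25 * bx + rng.normal(0, sy)
        h = make_harmonized(bx, sy, by, se_x=np.full(10, 1e-8))
        assert max_likelihood(h).theta == pytest.approx(ivw_fixed(h).theta, abs=1e-4)

    def test_noiseless_recovery(self):
        h = make_harmonized([0.05, -0.04], [1e-6, 1e-6], [0.015, -0.012],
                            se_x=[1e-6, 1e-6])
        assert max_likelihood(h).theta == pytest.approx(0.3, abs=1e-4)

    def test_null_coverage(self):
        """Under theta = 0, |theta_hat| < 2 se in >= 93% of seeds."""
        hits, n_seeds = 0, 200
        for seed in range(n_seeds):
            r = np.random.default_rng(1000 + seed)
            bx_true = r.uniform(0.03, 0.08, 30)
            sx = np.full(30, 0.005)
            sy = np.full(30, 0.01)
            h = make_harmonized(
                r.normal(bx_true, sx), sy, r.normal(0, sy), se_x=sx
            )
            est = max_likelihood(h)
            hits += abs(est.theta) < 2 * est.se
        assert hits / n_seeds >= 0.93


class TestEgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.03, 0.05, 0.08, 0.02])
        h = make_harmonized(bx, [0.01, 0.01, 0.02, 0.01], 0.4 * bx)
        res = mr_egger(h)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.slope.theta == pytest.approx(0.4)

    def test_constant_pleiotropy_in_intercept(self):
        bx = np.array([0.03, 0.05, 0.08, 0.02])
        h = make_harmonized(bx, [0.01, 0.01, 0.02, 0.01], 0.01 + 0.4 * bx)
        res = mr_egger(h)
        assert res.intercept == pytest.approx(0.01, abs=1e-12)
        assert res.intercept_ci_low < res.intercept < res.intercept_ci_high

    def test_matches_normal_equations_oracle(self, rng):
        bx = rng.uniform(0.02, 0.1, 12)
        sy = rng.uniform(0.005, 0.02, 12)
        by = 0.005 + 0.3 * bx + rng.normal(0, sy)
        res = mr_egger(make_harmonized(bx, sy, by))
        # hand-solved 2x2 weighted normal equations (orientation: bx >= 0 already)
        w = sy**-2.0
        A = np.array([[w.sum(), (w * bx).sum()], [(w * bx).sum(), (w * bx**2).sum()]])
        b = np.array([(w * by).sum(), (w * bx * by).sum()])
        intercept, slope = np.linalg.solve(A, b)
        assert res.intercept == pytest.approx(intercept, abs=1e-12)
        assert res.slope.theta == pytest.approx(slope, abs=1e-12)

    def test_orientation_invariance(self, rng):
        """Re-signing any instrument's (bx, by) pair leaves the fit unchanged."""
        bx = rng.uniform(0.02, 0.1, 6)
        sy = rng.uniform(0.005, 0.02, 6)
        by = 0.01 + 0.3 * bx + rng.normal(0, sy)
        flip = np.array([1, -1, 1, -1, -1, 1.0])
        a = mr_egger(make_harmonized(bx, sy, by))
        b = mr_egger(make_harmonized(bx * flip, sy, by * flip))
        assert a.slope.theta == pytest.approx(b.slope.theta)
        assert a.intercept == pytest.approx(b.intercept)

    def test_intercept_type_one_error_calibrated(self):
        """No-pleiotropy fixtures reject H0: intercept = 0 at ~ alpha."""
        n_reps, k, alpha = 500, 60, 0.05
        rejections = 0
        for seed in range(n_reps):
            r = np.random.default_rng(30_000 + seed)
            bx = r.uniform(0.03, 0.1, k)
            sy = np.full(k, 0.01)
            by = r.normal(0.3 * bx, sy)
            rejections += mr_egger(make_harmonized(bx, sy, by)).intercept_pvalue < alpha
        rate = rejections / n_reps
        se_binom = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert abs(rate - alpha) < 3 * se_binom + 0.01


class TestPresso:
    def test_zero_residuals_no_outliers(self):
        bx = np.array([0.03, 0.05, 0.08, 0.02, 0.06])
        h = make_harmonized(bx, np.full(5, 0.01), 0.4 * bx)
        res = mr_presso(h, n_sim=500, seed=1)
        assert res.global_pvalue == pytest.approx(1.0, abs=0.01)
        assert res.outliers == []

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_outlier_flagged(self, seed):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.03, 0.1, 10)
        sy = np.full(10, 0.01)
        by = 0.3 * bx + rng.normal(0, sy)
        by[4] += 20 * sy[4]
        res = mr_presso(make_harmonized(bx, sy, by), n_sim=1000, seed=seed)
        assert "rs4" in res.outliers

    def test_monte_carlo_stability(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.03, 0.1, 8)
        sy = np.full(8, 0.01)
        by = 0.3 * bx + rng.normal(0, 2 * sy)  # mild overdispersion
        h = make_harmonized(bx, sy, by)
        p1 = mr_presso(h, n_sim=1000, seed=1).global_pvalue
        p2 = mr_presso(h, n_sim=2000, seed=2).global_pvalue
        assert abs(p1 - p2) < 0.05


class TestLOO:
    def test_two_instruments_cross_ratios(self):
        h = make_harmonized([0.1, 0.2], [0.01, 0.01], [0.05, 0.04])
        out = dict(loo_estimates(h))
        assert out["rs0"].theta == pytest.approx(0.04 / 0.2)  # rs0 excluded
        assert out["rs1"].theta == pytest.approx(0.05 / 0.1)

    def test_identical_instruments_identical_estimates(self):
        h = make_harmonized(np.full(10, 0.05), np.full(10, 0.01), np.full(10, 0.02))
        full = ivw_fixed(h).theta
        for _, est in loo_estimates(h):
            assert est.theta == pytest.approx(full)

    def test_outlier_exclusion_moves_estimate_most(self, rng):
        bx = rng.uniform(0.03, 0.1, 9)
        sy = np.full(9, 0.01)
        by = 0.3 * bx + rng.normal(0, 0.2 * sy)
        by[6] += 15 * sy[6]
        h = make_harmonized(bx, sy, by)
        full = ivw_fixed(h).theta
        shifts = {snp: abs(est.theta - full) for snp, est in loo_estimates(h)}
        assert max(shifts, key=shifts.get) == "rs6"
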