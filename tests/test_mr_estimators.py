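import itertools

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrpipe.mr_estimators import (
    bh_fdr,
    egger,
    ivw,
    mode_estimate,
    mvmr_ivw,
    run_all_methods,
    weighted_median,
    _weighted_median_point,
)

from conftest import make_harmonized


class TestIVW:
    def test_hand_computed_weighted_average(self, simple_harmonized):
        r = ivw(simple_harmonized, effects_model="fixed")
        assert r.beta == pytest.approx(142.5 / 1125, rel=1e-6)   # 0.12667
        assert r.se == pytest.approx(1 / np.sqrt(1125), rel=1e-4)  # 0.02981

    def test_single_pair_rejected(self):
        hs = make_harmonized(ratios=[0.1], wald_ses=[0.05])
        with pytest.raises(ValueError):
            ivw(hs)

    def test_identical_ratios_random_equals_fixed(self):
        hs = make_harmonized(ratios=[0.1, 0.1, 0.1], wald_ses=[0.05, 0.04, 0.03])
        rf = ivw(hs, "fixed")
        rr = ivw(hs, "multiplicative_random")
        assert rf.beta == pytest.approx(0.1)
        assert rr.se == pytest.approx(rf.se)
        assert rr.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_equals_zero_intercept_wls(self):
        """IVW weighted average == weighted regression of beta_out on beta_exp through origin."""
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.3, 8)
        by = 0.2 * bx + rng.normal(0, 0.01, 8)
        sy = rng.uniform(0.005, 0.02, 8)
        hs = make_harmonized(beta_exp=bx, se_exp=np.full(8, 1e-4), beta_out=by, se_out=sy)
        r = ivw(hs, "fixed")
        wls = sm.WLS(by, bx, weights=1 / sy**2).fit()
        assert r.beta == pytest.approx(wls.params[0], rel=1e-10)

    def test_random_effects_never_tighter_than_fixed(self):
        hs = make_harmonized(ratios=[0.5, -0.2, 0.9, 0.1], wald_ses=[0.05, 0.04, 0.06, 0.05])
        assert ivw(hs).se >= ivw(hs, "fixed").se


class TestEgger:
    def test_exact_collinear_fit(self):
        hs = make_harmonized(beta_exp=[1, 2, 3], se_exp=[1e-4] * 3,
                             beta_out=[0.15, 0.25, 0.35], se_out=[0.05] * 3)
        r = egger(hs)
        assert r.beta == pytest.approx(0.1, rel=1e-9)
        assert r.egger_intercept == pytest.approx(0.05, rel=1e-9)

    def test_no_pleiotropy_matches_ivw(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.1, 0.5, 20)
        by = 0.1 * bx + rng.normal(0, 0.002, 20)
        hs = make_harmonized(beta_exp=bx, se_exp=np.full(20, 1e-4),
                             beta_out=by, se_out=np.full(20, 0.01))
        re = egger(hs)
        ri = ivw(hs)
        assert re.egger_intercept == pytest.approx(0.0, abs=0.005)
        assert re.beta == pytest.approx(ri.beta, abs=0.02)

    def test_two_pairs_rejected(self):
        hs = make_harmonized(ratios=[0.1, 0.2], wald_ses=[0.05, 0.05])
        with pytest.raises(ValueError):
            egger(hs)

    def test_matches_statsmodels_wls(self):
        """Slope/intercept agree with an independent WLS fit on oriented data."""
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.4, 15)
        by = 0.05 + 0.2 * bx + rng.normal(0, 0.02, 15)
        sy = rng.uniform(0.01, 0.03, 15)
        hs = make_harmonized(beta_exp=bx, se_exp=np.full(15, 1e-4), beta_out=by, se_out=sy)
        r = egger(hs)
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1 / sy**2).fit()
        assert r.egger_intercept == pytest.approx(fit.params[0], rel=1e-8)
        assert r.beta == pytest.approx(fit.params[1], rel=1e-8)


class TestWeightedMedian:
    def test_hand_interpolation(self):
        # weights 625, 400, 100 from SEs 0.04, 0.05, 0.1
        hs = make_harmonized(ratios=[0.1, 0.15, 0.2], wald_ses=[0.04, 0.05, 0.1])
        r = weighted_median(hs, n_boot=0)
        expected = 0.1 + (0.5 - 0.2778) / (0.7333 - 0.2778) * 0.05
        assert r.beta == pytest.approx(expected, abs=1e-4)  # 0.12439

    def test_all_equal(self):
        hs = make_harmonized(ratios=[0.07] * 4, wald_ses=[0.05, 0.04, 0.03, 0.02])
        assert weighted_median(hs, n_boot=0).beta == pytest.approx(0.07)

    def test_dominating_weight_limit(self):
        hs = make_harmonized(ratios=[0.3, 0.1, 0.5], wald_ses=[1e-5, 1.0, 1.0])
        assert weighted_median(hs, n_boot=0).beta == pytest.approx(0.3, abs=1e-6)

    def test_matches_grid_oracle(self):
        """Grid inversion of the mid-point weighted CDF agrees with the
        interpolated weighted median."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            k = int(rng.integers(3, 13))
            ratios = rng.normal(0.1, 0.2, k)
            ses = rng.uniform(0.02, 0.3, k)
            w = 1 / ses**2
            order = np.argsort(ratios)
            r_s, w_s = ratios[order], w[order]
            p = (np.cumsum(w_s) - w_s / 2) / w_s.sum()
            grid = np.linspace(ratios.min(), ratios.max(), 20001)
            cdf = np.interp(grid, r_s, p)
            oracle = grid[np.argmin(np.abs(cdf - 0.5))]
            est = _weighted_median_point(ratios, w)
            assert est == pytest.approx(oracle, abs=2 * (grid[1] - grid[0]) + 1e-9)

    def test_bootstrap_se_reproducible(self):
        hs = make_harmonized(ratios=[0.1, 0.2, 0.15, 0.05], wald_ses=[0.05] * 4)
        r1 = weighted_median(hs, n_boot=200, seed=11)
        r2 = weighted_median(hs, n_boot=200, seed=11)
        assert r1.se == r2.se and r1.se > 0


class TestModeEstimators:
    def test_degenerate_spread(self):
        hs = make_harmonized(ratios=[0.12] * 5, wald_ses=[0.05] * 5)
        r = mode_estimate(hs, "simple", n_boot=0)
        assert r.beta == pytest.approx(0.12)
        assert r.se == 0.0

    def test_outlier_ignored_by_mode(self):
        hs = make_harmonized(ratios=[0.10, 0.11, 0.12, 0.9], wald_ses=[0.05] * 4)
        r = mode_estimate(hs, "simple", n_boot=0)
        assert 0.09 <= r.beta <= 0.13

    def test_weighted_downweights_weak_outlier(self):
        hs = make_harmonized(ratios=[0.10, 0.11, 0.12, 0.9],
                             wald_ses=[0.02, 0.02, 0.02, 5.0])
        rw = mode_estimate(hs, "weighted", n_boot=0)
        rs = mode_estimate(make_harmonized(ratios=[0.10, 0.11, 0.12],
                                           wald_ses=[0.02, 0.02, 0.02]),
                           "simple", n_boot=0)
        assert rw.beta == pytest.approx(rs.beta, abs=0.02)


class TestMVMR:
    def test_single_exposure_reduces_to_ivw(self):
        import pandas as pd
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.3, 10)
        by = 0.15 * bx + rng.normal(0, 0.005, 10)
        sy = np.full(10, 0.01)
        hs = make_harmonized(beta_exp=bx, se_exp=np.full(10, 1e-4), beta_out=by, se_out=sy)
        df = pd.DataFrame({"variant_id": [f"rs{i}" for i in range(10)],
                           "beta_x": bx, "se_x": 1e-4, "beta_out": by, "se_out": sy})
        res = mvmr_ivw(df, exposure_cols=["beta_x"])[0]
        r = ivw(hs, "fixed")
        assert res.beta == pytest.approx(r.beta, rel=1e-10)

    def test_exact_two_exposure_recovery(self):
        import pandas as pd
        rng = np.random.default_rng(6)
        x1 = rng.uniform(0.1, 0.5, 8)
        x2 = rng.uniform(0.1, 0.5, 8)
        y = 0.1 * x1 + 0.2 * x2
        df = pd.DataFrame({"beta_a": x1, "beta_b": x2, "beta_out": y, "se_out": 0.01})
        res = mvmr_ivw(df, exposure_cols=["beta_a", "beta_b"])
        assert res[0].beta == pytest.approx(0.1, rel=1e-9)
        assert res[1].beta == pytest.approx(0.2, rel=1e-9)

    def test_collinear_exposures_rejected(self):
        import pandas as pd
        x1 = np.linspace(0.1, 0.5, 8)
        df = pd.DataFrame({"beta_a": x1, "beta_b": 2 * x1,
                           "beta_out": 0.3 * x1, "se_out": 0.01})
        with pytest.raises(ValueError, match="[Cc]ollinear|rank"):
            mvmr_ivw(df, exposure_cols=["beta_a", "beta_b"])

    def test_too_few_instruments(self):
        import pandas as pd
        df = pd.DataFrame({"beta_a": [0.1, 0.2, 0.3], "beta_b": [0.3, 0.1, 0.2],
                           "beta_out": [0.05, 0.04, 0.06], "se_out": 0.01})
        with pytest.raises(ValueError, match="instruments"):
            mvmr_ivw(df, exposure_cols=["beta_a", "beta_b"])


class TestBHFDR:
    @staticmethod
    def brute_force(pvals):
        """Literal step-up definition: q(i) = min_{j>=i} p(j)·m/j on the sorted scale."""
        p = np.asarray(pvals, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        for rank_i, idx in enumerate(order):
            candidates = [p[order[j]] * m / (j + 1) for j in range(rank_i, m)]
            q[idx] = min(min(candidates), 1.0)
        return q

    def test_worked_example(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.04])
        np.testing.assert_allclose(q, [0.004, 0.02, 0.8 / 30, 0.04], rtol=1e-9)

    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_all_permutations_of_six(self):
        base = [0.001, 0.008, 0.039, 0.041, 0.27, 0.8]
        for perm in itertools.permutations(base):
            np.testing.assert_allclose(bh_fdr(list(perm)), self.brute_force(perm), rtol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        p = rng.uniform(size=25)
        np.testing.assert_allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12)

    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=1, max_size=15))
    @settings(deadline=None, derandomize=True)
    def test_qvalues_bounded_and_order_preserving(self, pvals):
        q = bh_fdr(pvals)
        p = np.array(pvals)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestRunAll:
    def test_full_battery(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.1, 0.4, 8)
        hs = make_harmonized(beta_exp=bx, se_exp=np.full(8, 0.01),
                             beta_out=0.1 * bx + rng.normal(0, 0.005, 8),
                             se_out=rng.uniform(0.005, 0.02, 8))
        res = run_all_methods(hs, n_boot=50)
        assert [r.method for r in res] == ["ivw", "egger", "weighted_median",
                                           "simple_mode", "weighted_mode"]
        assert all(np.isfinite(r.beta) for r in res)
        assert res[0].extra["direction_agreement"] is True

    def test_two_pairs_only_ivw(self):
        hs = make_harmonized(ratios=[0.1, 0.2], wald_ses=[0.05, 0.05])
        res = run_all_methods(hs)
        assert np.isfinite(res[0].beta)
        assert all("skipped" in r.extra for r in res[1:])

    def test_or_ci_transform(self, simple_harmonized):
        r = ivw(simple_harmonized)
        assert r.ci_low < r.or_ < r.ci_high
        assert r.or_ == pytest.approx(np.exp(r.beta))
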