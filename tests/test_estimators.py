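"""MR estimators against closed-form oracles and analytic limiting cases."""

import numpy as np
import pytest
from scipy import stats

from mr2s.estimators import (
    EggerEstimator, IVWEstimator, RAPSEstimator, WeightedMedianEstimator,
    cochran_q, egger, ivw, leave_one_out, raps, weighted_median,
    estimates_to_frame,
)

from conftest import as_harmonized, draw_instruments, wls_oracle


def _h(bx, sx, by, sy):
    cols = np.broadcast_arrays(np.asarray(bx, float), np.asarray(sx, float),
                               np.asarray(by, float), np.asarray(sy, float))
    return np.column_stack(cols)


class TestIVW:
    def test_single_instrument_is_wald_ratio(self):
        e = ivw(_h([0.5], [0.01], [0.1], [0.02]), re_mode="fixed")
        assert e.beta == pytest.approx(0.2)
        assert e.n_snps == 1

    def test_zero_outcome_betas_give_null_or(self):
        e = ivw(_h([0.2, 0.3, 0.4], 0.01, [0.0, 0.0, 0.0], 0.02))
        assert e.beta == 0.0 and e.or_ == 1.0

    def test_all_zero_exposure_is_error(self):
        with pytest.raises(ValueError, match="identified"):
            ivw(_h([0.0, 0.0], 0.01, [0.1, 0.2], 0.02))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_wls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = draw_instruments(rng, 4 + seed, theta=0.1)
        bx, sx, by, sy = X.T
        coefs, fixed_se, _ = wls_oracle(bx, by, 1 / sy**2, intercept=False)
        e = ivw(X, re_mode="fixed")
        assert e.beta == pytest.approx(float(coefs[0]), rel=1e-10)
        assert e.se == pytest.approx(float(fixed_se[0]), rel=1e-10)

    def test_multiplicative_se_never_below_fixed(self, rng):
        X = draw_instruments(rng, 20, theta=0.05,
                             alpha=rng.normal(0, 0.05, 20))
        assert ivw(X).se >= ivw(X, re_mode="fixed").se

    def test_heterogeneity_stat_matches_cochran_q(self, rng):
        X = draw_instruments(rng, 15, theta=0.1)
        e = ivw(X, re_mode="fixed")
        q, p = cochran_q(X, e.beta)
        assert e.extra["Q"] == pytest.approx(q)
        assert e.extra["het_p"] == pytest.approx(p)


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.02 + 0.3 * bx
        e = egger(_h(bx, 0.01, by, 0.02))
        assert e.beta == pytest.approx(0.3, abs=1e-10)
        assert e.extra["intercept"] == pytest.approx(0.02, abs=1e-10)

    def test_proportional_data_zero_intercept(self):
        bx = np.array([0.1, 0.25, 0.4, 0.6])
        e = egger(_h(bx, 0.01, 0.2 * bx, 0.02))
        assert e.extra["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_orientation_invariance_to_exposure_sign(self, rng):
        X = draw_instruments(rng, 12, theta=0.1)
        flip = rng.random(12) < 0.5
        Y = X.copy()
        Y[flip, 0] *= -1
        Y[flip, 2] *= -1
        e0, e1 = egger(X), egger(Y)
        assert e1.beta == pytest.approx(e0.beta, rel=1e-12)
        assert e1.extra["intercept"] == pytest.approx(e0.extra["intercept"], rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_wls_oracle_with_intercept(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = 5 + seed
        X = draw_instruments(rng, n, theta=0.1, alpha=rng.normal(0.02, 0.03, n))
        bx, sx, by, sy = X.T
        sign = np.where(bx < 0, -1.0, 1.0)
        coefs, fixed_se, scale = wls_oracle(sign * bx, sign * by, 1 / sy**2,
                                            intercept=True)
        infl = np.sqrt(max(1.0, scale))
        e = egger(X)
        assert e.beta == pytest.approx(float(coefs[1]), rel=1e-10)
        assert e.extra["intercept"] == pytest.approx(float(coefs[0]), rel=1e-10)
        assert e.se == pytest.approx(float(fixed_se[1] * infl), rel=1e-10)
        assert e.extra["intercept_se"] == pytest.approx(float(fixed_se[0] * infl),
                                                        rel=1e-10)

    def test_too_few_instruments_error(self):
        with pytest.raises(ValueError):
            egger(_h([0.1, 0.2], 0.01, [0.1, 0.2], 0.02))

    def test_constant_exposure_error(self):
        with pytest.raises(ValueError, match="variance"):
            egger(_h([0.3, 0.3, 0.3], 0.01, [0.1, 0.15, 0.2], 0.02))


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        # ratios 0.2, 0.4, 0.6 with equal weights -> middle one
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.2, 0.4, 0.6])
        e = weighted_median(_h(bx, 1e-6, by, 1.0), n_boot=100, seed=0)
        assert e.beta == pytest.approx(0.4)

    def test_degenerate_all_ratios_equal(self):
        bx = np.array([0.2, 0.3, 0.5])
        e = weighted_median(_h(bx, 1e-10, 0.7 * bx, 1e-10), n_boot=200, seed=0)
        assert e.beta == pytest.approx(0.7, abs=1e-6)
        assert e.se < 1e-8

    def test_unequal_weights_match_interpolation_oracle(self):
        # hand-computable: cumulative p_j = (sum_{i<=j} w_i - w_j/2) / W
        ratios = np.array([0.1, 0.2, 0.3, 0.5, 0.8])
        bx = np.array([1.0, 2.0, 1.0, 3.0, 1.0])
        sy = np.array([1.0, 1.0, 2.0, 1.0, 1.0])
        by = ratios * bx
        w = bx**2 / sy**2
        p = (np.cumsum(w) - w / 2) / w.sum()
        expected = float(np.interp(0.5, p, ratios))
        e = weighted_median(_h(bx, 1e-9, by, sy), n_boot=100, seed=0)
        assert e.beta == pytest.approx(expected, abs=1e-9)

    def test_zero_exposure_instrument_excluded_with_warning(self):
        X = _h([0.0, 0.3, 0.4, 0.5], 0.01, [0.1, 0.06, 0.08, 0.10], 0.02)
        with pytest.warns(UserWarning, match="beta_exp == 0"):
            e = weighted_median(X, n_boot=100, seed=0)
        assert e.n_snps == 3

    def test_seed_is_mandatory_and_reproducible(self, rng):
        X = draw_instruments(rng, 10, theta=0.1)
        with pytest.raises(ValueError, match="seed"):
            weighted_median(X)
        a = weighted_median(X, seed=7)
        b = weighted_median(X, seed=7)
        assert a.se == b.se and a.beta == b.beta

    def test_estimate_between_extreme_ratios(self, rng):
        X = draw_instruments(rng, 15, theta=0.2)
        r = X[:, 2] / X[:, 0]
        e = weighted_median(X, n_boot=50, seed=0)
        assert r.min() <= e.beta <= r.max()


class TestRAPS:
    def test_l2_no_overdispersion_reduces_to_ivw_when_exposure_exact(self, rng):
        X = draw_instruments(rng, 20, theta=0.1)
        X[:, 1] = 0.0  # exposure measured without error
        e = raps(X, loss="l2", overdispersion=False)
        assert e.beta == pytest.approx(ivw(X, re_mode="fixed").beta, rel=1e-8)

    @pytest.mark.parametrize("loss", ["l2", "huber"])
    def test_exact_proportional_data_any_loss(self, loss):
        bx = np.array([0.2, 0.35, 0.4, 0.55])
        X = _h(bx, 0.02, 0.25 * bx, 0.03)
        e = raps(X, loss=loss, overdispersion=False)
        assert e.beta == pytest.approx(0.25, abs=1e-9)

    def test_overdispersion_tau2_nonnegative_and_detects_spread(self, rng):
        X = draw_instruments(rng, 40, theta=0.1,
                             alpha=rng.normal(0, 0.05, 40))
        e = raps(X, loss="l2", overdispersion=True)
        assert e.extra["tau2"] > 0
        clean = draw_instruments(rng, 40, theta=0.1)
        e2 = raps(clean, loss="l2", overdispersion=True)
        assert e2.extra["tau2"] < e.extra["tau2"]

    def test_simulation_recovery_with_two_sided_noise(self):
        # independent oracle: truth known by construction
        theta = 0.1
        reps = 200
        ests = np.empty(reps)
        for i in range(reps):
            rng = np.random.default_rng(3000 + i)
            X = draw_instruments(rng, 50, theta=theta, n_exp=2000)
            ests[i] = raps(X, loss="huber", overdispersion=True).beta
        mc_se = ests.std(ddof=1) / np.sqrt(reps)
        assert abs(ests.mean() - theta) < 3 * mc_se


class TestScaleEquivariance:
    """Rescaling the exposure (beta_exp, se_exp times c) divides every
    causal estimate by c."""

    @pytest.mark.parametrize("method", ["ivw", "egger", "weighted_median", "raps"])
    def test_rescaling_exposure(self, method, rng):
        X = draw_instruments(rng, 12, theta=0.15)
        c = 3.7
        Y = X.copy()
        Y[:, 0] *= c
        Y[:, 1] *= c
        kw = {"seed": 5} if method == "weighted_median" else {}
        fn = {"ivw": ivw, "egger": egger,
              "weighted_median": weighted_median, "raps": raps}[method]
        assert fn(Y, **kw).beta == pytest.approx(fn(X, **kw).beta / c, rel=1e-6)


class TestCochranQ:
    def test_identical_ratios_zero_q(self):
        bx = np.array([0.2, 0.4, 0.5])
        q, p = cochran_q(_h(bx, 0.01, 0.3 * bx, 0.02), 0.3)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_two_instruments_hand_computed(self):
        # ratios 0.5 and 0.25; w_j = (se_out/beta_exp)^-2 = (bx/sy)^2
        X = _h([0.2, 0.4], 0.01, [0.1, 0.1], [0.05, 0.02])
        beta = 0.3
        w = np.array([(0.2 / 0.05) ** 2, (0.4 / 0.02) ** 2])
        ratios = np.array([0.5, 0.25])
        expected = float(np.sum(w * (ratios - beta) ** 2))
        q, p = cochran_q(X, beta)
        assert q == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(expected, 1)), rel=1e-12)

    def test_q_grows_as_one_ratio_moves_away(self):
        bx = np.array([0.3, 0.3, 0.3])
        qs = []
        for shift in [0.0, 0.05, 0.1, 0.2]:
            by = 0.2 * bx + np.array([0.0, 0.0, shift])
            qs.append(cochran_q(_h(bx, 0.01, by, 0.02), 0.2)[0])
        assert qs == sorted(qs) and qs[-1] > qs[0]


class TestLeaveOneOut:
    def test_identical_instruments_all_equal_overall(self):
        X = _h([0.3] * 4, 0.01, [0.06] * 4, 0.02)
        res = leave_one_out(X, re_mode="fixed")
        for e in res.per_snp.values():
            assert e.beta == pytest.approx(res.overall.beta)
            assert e.n_snps == 3

    def test_planted_outlier_shifts_most(self, rng):
        X = draw_instruments(rng, 10, theta=0.1)
        X[3, 2] += 12 * X[3, 3]  # displace one outcome beta
        res = leave_one_out(X, re_mode="fixed")
        ids = list(res.per_snp)
        shifts = {k: abs(v.beta - res.overall.beta)
                  for k, v in res.per_snp.items()}
        assert max(shifts, key=shifts.get) == ids[3]

    def test_three_instruments_three_pairs(self, rng):
        X = draw_instruments(rng, 3, theta=0.0)
        res = leave_one_out(X)
        assert len(res.per_snp) == 3
        assert all(e.n_snps == 2 for e in res.per_snp.values())
        frame = res.to_frame()
        assert frame["excluded"].tolist()[-1] == "All"


class TestSklearnSurface:
    def test_get_set_params_and_fitted_attributes(self, rng):
        X = draw_instruments(rng, 8, theta=0.1)
        est = IVWEstimator(re_mode="fixed")
        assert est.get_params() == {"re_mode": "fixed"}
        est.set_params(re_mode="multiplicative").fit(X)
        for attr in ("beta_", "se_", "ci_low_", "ci_high_", "pval_", "or_",
                     "n_snps_"):
            assert hasattr(est, attr)
        assert est.estimate_.method == "ivw"

    def test_estimator_frame_serialization(self, rng):
        X = draw_instruments(rng, 8, theta=0.1)
        frame = estimates_to_frame([ivw(X), egger(X)])
        assert list(frame["method"]) == ["ivw", "egger"]
        assert {"beta", "se", "pval", "or", "n_snps"} <= set(frame.columns)

    def test_accepts_harmonized_container_and_dataframe(self, rng):
        X = draw_instruments(rng, 8, theta=0.1)
        h = as_harmonized(X)
        assert ivw(h).beta == pytest.approx(ivw(X).beta)
        assert ivw(h.df).beta == pytest.approx(ivw(X).beta)
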