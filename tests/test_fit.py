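"""Estimation tests: Newton fits against independent oracles, EM, Wald/HWE/LR."""

import numpy as np
import pytest
from scipy import optimize, stats

from triadglm.cells import MD_AGG, MD_CELLS, TRIAD_CELLS, CountTable
from triadglm.design import ModelSpec, build_design, expected_probs, theta_from_rrs
from triadglm.fit import (
    FitResult,
    fit_complete,
    fit_with_missing,
    hwe_test,
    lr_test,
    marginal_loglik,
    wald_effects,
)
from triadglm.simulate import SimConfig, simulate_counts


def multinomial_ll(y, theta, design):
    """Independent multinomial log-likelihood (intercept-free parameterization)."""
    eta = design.X[:, 1:] @ theta + design.offset
    eta = eta - eta.max()
    pi = np.exp(eta) / np.exp(eta).sum()
    mask = y > 0
    return float(y[mask] @ np.log(pi[mask]))


def scipy_max_ll(y, design):
    """Oracle: maximize the multinomial likelihood with scipy (BFGS + Nelder polish)."""
    fun = lambda t: -multinomial_ll(y, t, design)
    res = optimize.minimize(fun, np.zeros(design.n_params - 1), method="BFGS")
    res = optimize.minimize(fun, res.x, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return -res.fun


class TestFitComplete:
    @pytest.mark.parametrize(
        "spec,rrs",
        [
            (ModelSpec(fetal="dose"), {"gamma_c": 0.7}),
            (ModelSpec(fetal="free", parental_interaction="complementary"),
             {"gamma_c": 0.8, "gamma_c12": 1.3, "beta_mf": 1.8}),
            (ModelSpec(fetal="none", parental_interaction="threshold"), {"beta_mf": 1.4}),
        ],
    )
    def test_recovers_generating_params_from_expected_counts(self, spec, rrs):
        design = build_design(spec)
        theta0 = theta_from_rrs(design, 0.3, rrs)
        y = 1000.0 * expected_probs(theta0, design)
        fit = fit_complete(y, design)
        assert fit.status == "converged"
        np.testing.assert_allclose(fit.theta[1:], theta0[1:], atol=1e-8)

    def test_matches_scipy_oracle(self, rng):
        design = build_design(ModelSpec(fetal="free", parental_interaction="complementary"))
        for _ in range(10):
            y = rng.integers(1, 60, size=15).astype(float)
            fit = fit_complete(y, design)
            assert fit.status == "converged"
            assert fit.loglik == pytest.approx(scipy_max_ll(y, design), abs=1e-6)

    def test_matches_grid_oracle(self, rng):
        # 2 free non-intercept params; brute-force 400x400 grid over (a_m, a_f)
        design = build_design(ModelSpec(fetal="none", parental_interaction="none"))
        y = rng.integers(0, 12, size=15).astype(float)
        y[0] += 1  # guard against an all-zero table
        fit = fit_complete(y, design)
        grid = np.linspace(-1.5, 1.5, 400)
        best = -np.inf
        eta0 = design.offset
        xm = design.X[:, 1]
        xf = design.X[:, 2]
        mask = y > 0
        for am in grid:
            etas = eta0[None, :] + am * xm[None, :] + grid[:, None] * xf[None, :]
            etas -= etas.max(axis=1, keepdims=True)
            lls = (y[mask] * (etas[:, mask] - np.log(np.exp(etas).sum(axis=1))[:, None])).sum(axis=1)
            best = max(best, lls.max())
        assert best <= fit.loglik + 1e-9
        assert fit.loglik - best < 1e-3

    def test_scale_invariance(self, rng, joint_design):
        y = rng.integers(1, 40, size=15).astype(float)
        f1 = fit_complete(y, joint_design)
        f2 = fit_complete(10.0 * y, joint_design)
        np.testing.assert_allclose(f1.theta[1:], f2.theta[1:], atol=1e-7)

    def test_null_wald_calibration(self, rng, dose_design):
        reps, n, hits = 400, 4000, 0
        theta0 = theta_from_rrs(dose_design, 0.3)
        pi = expected_probs(theta0, dose_design)
        for _ in range(reps):
            y = rng.multinomial(n, pi).astype(float)
            fit = fit_complete(y, dose_design)
            z = fit.coef("gamma_c") / fit.se("gamma_c")
            hits += abs(z) > stats.norm.isf(0.025)
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < 3 * se

    def test_all_zero_rejected(self, dose_design):
        with pytest.raises(ValueError):
            fit_complete(np.zeros(15), dose_design)

    def test_separation_flagged_as_boundary(self, joint_design):
        # no complementary couples at all: beta_mf diverges to -inf
        y = np.ones(15)
        comp = joint_design.X[:, joint_design.column_index("beta_mf")] > 0
        y[comp] = 0.0
        fit = fit_complete(y, joint_design, max_iter=200)
        assert fit.status == "boundary"
        assert "beta_mf" in fit.boundary_coefficients


class TestMarginalLoglik:
    def test_triads_only_equals_multinomial(self, rng, dose_design):
        y = rng.integers(0, 20, 15).astype(float)
        table = CountTable(triad=y)
        theta = theta_from_rrs(dose_design, 0.4, {"gamma_c": 1.3})
        assert marginal_loglik(theta, table, dose_design) == pytest.approx(
            multinomial_ll(y, theta[1:], dose_design), abs=1e-10
        )

    def test_dyad_contribution_is_compatibility_sum(self, dose_design):
        table = CountTable()
        idx = [d.key for d in MD_CELLS].index((0, 0))
        table.md[idx] = 1.0
        theta = theta_from_rrs(dose_design, 0.5)
        pi = expected_probs(theta, dose_design)
        keys = [c.key for c in TRIAD_CELLS]
        expected = np.log(pi[keys.index((0, 0, 0))] + pi[keys.index((0, 1, 0))])
        assert marginal_loglik(theta, table, dose_design) == pytest.approx(expected, abs=1e-12)

    def test_logsum_exceeds_any_completion(self, rng, dose_design):
        theta = theta_from_rrs(dose_design, 0.3, {"gamma_c": 0.6})
        pi = expected_probs(theta, dose_design)
        table = CountTable()
        table.md[2] = 3.0
        ll = marginal_loglik(theta, table, dose_design)
        for cell in MD_CELLS[2].compatible_cells:
            assert ll >= 3.0 * np.log(pi[cell]) - 1e-12


class TestEM:
    def test_no_dyads_equals_fit_complete(self, rng, joint_design):
        y = rng.integers(1, 30, 15).astype(float)
        table = CountTable(triad=y)
        em = fit_with_missing(table, joint_design)
        direct = fit_complete(y, joint_design)
        np.testing.assert_array_equal(em.theta, direct.theta)
        np.testing.assert_array_equal(em.covariance, direct.covariance)

    def test_monotone_trajectory(self, rng, joint_design):
        cfg = SimConfig(n_triads=500, n_md=300, n_fd=100, p2=0.2,
                        true_effects={"interaction": 1.8}, seed=11)
        table = simulate_counts(cfg, joint_design.spec)
        fit = fit_with_missing(table, joint_design)
        assert fit.status == "converged"
        diffs = np.diff(fit.em_trajectory)
        assert (diffs > -1e-9).all()

    def test_masked_fathers_recover_truth(self, rng, joint_design):
        # criterion: simulate triads, mask 30% of fathers, refit via EM
        rrs = {"fetal_single": 1.0, "fetal_double": 1.0, "interaction": 1.6}
        n = 5000
        cfg = SimConfig(n_triads=n, p2=0.25, true_effects=rrs, seed=7)
        full = simulate_counts(cfg, joint_design.spec)
        # mask: move a binomial 30% share of each triad cell into md cells
        masked = CountTable(triad=full.triad.copy())
        for i, cell in enumerate(TRIAD_CELLS):
            k = rng.binomial(int(full.triad[i]), 0.3)
            masked.triad[i] -= k
            j = np.nonzero(MD_AGG[:, i])[0][0]
            masked.md[j] += k
        fit = fit_with_missing(masked, joint_design)
        assert fit.status == "converged"
        truth = np.log(1.6)
        est, se = fit.coef("beta_mf"), fit.se("beta_mf")
        assert abs(est - truth) < 3 * se

    def test_small_masking_close_to_complete_fit(self, rng, joint_design):
        cfg = SimConfig(n_triads=4000, p2=0.3, seed=3)
        full = simulate_counts(cfg, joint_design.spec)
        masked = CountTable(triad=full.triad.copy())
        i = int(np.argmax(masked.triad))
        masked.triad[i] -= 2
        masked.md[np.nonzero(MD_AGG[:, i])[0][0]] += 2
        em = fit_with_missing(masked, joint_design)
        direct = fit_complete(full.triad, joint_design)
        np.testing.assert_allclose(em.theta[1:], direct.theta[1:], atol=0.05)

    def test_empty_table_rejected(self, joint_design):
        with pytest.raises(ValueError):
            fit_with_missing(CountTable(), joint_design)


class TestWaldEffects:
    def _fake_fit(self, columns, theta, cov):
        return FitResult(
            theta=np.array(theta), columns=tuple(columns), covariance=np.array(cov),
            loglik=0.0, status="converged", n_iter=1,
        )

    def test_null_effect_ci(self):
        fit = self._fake_fit(
            ["intercept", "a_m", "a_f", "gamma_c"],
            [0.0, 0.0, 0.0, 0.0],
            np.diag([1.0, 1.0, 1.0, 0.01]),
        )
        eff = wald_effects(fit).rr_fetal_single
        assert eff.estimate == pytest.approx(1.0)
        assert eff.ci_low == pytest.approx(0.822, abs=5e-4)
        assert eff.ci_high == pytest.approx(1.217, abs=5e-4)
        assert eff.p == pytest.approx(1.0)

    def test_exp_log_identity(self):
        fit = self._fake_fit(
            ["intercept", "a_m", "a_f", "gamma_c"],
            [0.0, 0.0, 0.0, np.log(0.75)],
            np.diag([1.0, 1.0, 1.0, 0.04]),
        )
        assert wald_effects(fit).rr_fetal_single.estimate == pytest.approx(0.75)

    def test_double_dose_multiplicative_limit(self):
        fit = self._fake_fit(
            ["intercept", "a_m", "a_f", "gamma_c", "gamma_c12"],
            [0.0, 0.0, 0.0, np.log(2.0), 0.0],
            np.diag([1.0, 1.0, 1.0, 0.01, 0.01]),
        )
        eff = wald_effects(fit)
        assert eff.rr_fetal_double.estimate == pytest.approx(4.0)

    def test_a_diff(self):
        fit = self._fake_fit(
            ["intercept", "a_m", "a_f"],
            [0.0, 0.5, 0.2],
            np.diag([1.0, 0.01, 0.01]),
        )
        eff = wald_effects(fit).a_diff
        assert eff.estimate == pytest.approx(0.3)
        assert eff.ci_low < 0.3 < eff.ci_high

    def test_requires_covariance(self):
        fit = FitResult(
            theta=np.zeros(3), columns=("intercept", "a_m", "a_f"), covariance=None,
            loglik=0.0, status="rank-deficient", n_iter=1,
        )
        with pytest.raises(ValueError):
            wald_effects(fit)


class TestHWE:
    def test_exact_proportions(self):
        res = hwe_test(25, 50, 25)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed(self):
        # expected 25/50/25 at p=0.5: chi2 = 1 + 2 + 1 = 4
        res = hwe_test(30, 40, 30)
        assert res.chi2 == pytest.approx(4.0, abs=1e-12)
        assert res.p == pytest.approx(0.0455, abs=2e-4)

    def test_monomorphic_degenerate(self):
        res = hwe_test(100, 0, 0)
        assert res.degenerate
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


class TestLRTest:
    def _fit(self, columns, loglik):
        return FitResult(
            theta=np.zeros(len(columns)), columns=tuple(columns), covariance=None,
            loglik=loglik, status="converged", n_iter=1,
        )

    def test_identical_fits(self):
        f = self._fit(["intercept", "a_m", "a_f"], -10.0)
        assert lr_test(f, f) == 1.0

    def test_chi2_quantile(self):
        full = self._fit(["intercept", "a_m", "a_f", "gamma_c"], -10.0)
        reduced = self._fit(["intercept", "a_m", "a_f"], -10.0 - 3.841459 / 2.0)
        assert lr_test(full, reduced) == pytest.approx(0.05, abs=1e-6)

    def test_non_nested_rejected(self):
        full = self._fit(["intercept", "a_m", "a_f", "gamma_c"], -10.0)
        other = self._fit(["intercept", "a_m", "a_f", "beta_mf"], -11.0)
        with pytest.raises(ValueError):
            lr_test(full, other)

    def test_negative_delta_clipped(self):
        full = self._fit(["intercept", "a_m", "a_f", "gamma_c"], -10.5)
        reduced = self._fit(["intercept", "a_m", "a_f"], -10.0)
        assert lr_test(full, reduced) == pytest.approx(1.0)

    def test_null_calibration(self, rng):
        # data under the reduced model: LR p-values roughly uniform
        full_d = build_design(ModelSpec(fetal="dose", parental_interaction="complementary"))
        red_d = build_design(ModelSpec(fetal="dose", parental_interaction="none"))
        theta0 = theta_from_rrs(red_d, 0.3, {"gamma_c": 0.3})
        pi = expected_probs(theta0, red_d)
        ps = []
        for _ in range(300):
            y = rng.multinomial(3000, pi).astype(float)
            ps.append(lr_test(fit_complete(y, full_d), fit_complete(y, red_d)))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestParameterRecovery:
    @pytest.mark.parametrize(
        "spec,rrs",
        [
            (ModelSpec(fetal="dose"), {"fetal_single": 1.3}),
            (ModelSpec(fetal="free", parental_interaction="complementary"),
             {"fetal_single": 1.2, "fetal_double": 1.8, "interaction": 1.5}),
            (ModelSpec(fetal="none", parental_interaction="threshold"),
             {"interaction": 1.4}),
        ],
    )
    def test_low_bias_at_large_n(self, spec, rrs):
        design = build_design(spec)
        cfg = SimConfig(n_triads=50_000, p2=0.3, true_effects=rrs)
        from triadglm.simulate import cell_distribution, effect_log_rrs

        pi = cell_distribution(spec, rrs, 0.3)
        truth = effect_log_rrs(spec, rrs)
        rng = np.random.default_rng(99)
        sums = {k: 0.0 for k in truth}
        reps = 200
        for _ in range(reps):
            y = rng.multinomial(cfg.n_triads, pi).astype(float)
            fit = fit_complete(y, design)
            for k in sums:
                sums[k] += fit.coef(k)
        for k, target in truth.items():
            assert abs(sums[k] / reps - target) < 0.02, k
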