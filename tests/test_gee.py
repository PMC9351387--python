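"""Standard and extended GEE estimation."""

import numpy as np
import pytest
import statsmodels.api as sm

from countraj import (
    CorrelationSpec,
    CountSeries,
    PowerSpec,
    SimSpec,
    ThetaParams,
    fit_gee,
    loglike,
    moment_rho,
    simulate_series,
)
from countraj.basis import disp_design, evaluate_model, mean_design
from countraj.correlation import corr_matrix
from countraj.gee import gee_hessian_blocks, gee_score_beta, gee_score_dispersion

IND = CorrelationSpec("ind")
AR1 = CorrelationSpec("ar1")


@pytest.fixture
def random_setup(ar1_series):
    spec = PowerSpec(mean_powers=(0.5,), disp_powers=(1.0,))
    rho = 0.35
    theta = ThetaParams([0.4, 0.08], [0.15, 0.01], rho)
    state = evaluate_model(ar1_series, spec, theta)
    X = mean_design(ar1_series, spec)
    Xp = disp_design(ar1_series, spec)
    R = corr_matrix(AR1, rho, ar1_series.times)
    return ar1_series, spec, theta, state, X, Xp, R


class TestScoresAndBlocks:
    def test_zero_residuals_zero_beta_score(self, random_setup):
        s, spec, theta, state, X, Xp, R = random_setup
        state.resid = np.zeros(s.n)
        Sigma = np.diag(state.sd_ext) @ R @ np.diag(state.sd_ext)
        np.testing.assert_allclose(gee_score_beta(state, X, Sigma), 0.0, atol=1e-12)

    def test_beta_score_matches_dense_oracle(self, random_setup):
        s, spec, theta, state, X, Xp, R = random_setup
        Sigma = np.diag(state.sd_ext) @ R @ np.diag(state.sd_ext)
        D = X * state.mu[:, None]
        expected = D.T @ np.linalg.inv(Sigma) @ state.resid
        np.testing.assert_allclose(gee_score_beta(state, X, Sigma), expected, rtol=1e-8)

    def test_ind_constant_dispersion_simplification(self, ar1_series):
        # with R = I and phi0 constant, g(beta) = X'(y - mu)/phi0
        spec = PowerSpec(mean_powers=(0.5,))
        phi0 = 1.7
        theta = ThetaParams([0.4, 0.08], [np.log(phi0)])
        eval_spec = PowerSpec(mean_powers=(0.5,), offsets_in_dispersion=False)
        state = evaluate_model(ar1_series, eval_spec, theta)
        X = mean_design(ar1_series, spec)
        Sigma = np.diag(state.var_ext)
        np.testing.assert_allclose(
            gee_score_beta(state, X, Sigma), X.T @ state.resid / phi0, rtol=1e-10
        )

    def test_dispersion_score_zero_residual_limit(self, random_setup):
        s, spec, theta, state, X, Xp, R = random_setup
        state.stde = np.zeros(s.n)
        Rinv = np.linalg.inv(R)
        np.testing.assert_allclose(
            gee_score_dispersion(state, Xp, Rinv), -Xp.sum(axis=0) / 2.0
        )

    def test_intercept_only_dispersion_scalar_reduction(self, ar1_series):
        spec = PowerSpec(mean_powers=(0.5,))
        theta = ThetaParams([0.4, 0.08], [0.3])
        state = evaluate_model(ar1_series, spec, theta)
        Xp = disp_design(ar1_series, spec)
        g = gee_score_dispersion(state, Xp, np.eye(ar1_series.n))
        assert g[0] == pytest.approx((np.sum(state.stde**2) - ar1_series.n) / 2)

    def test_dispersion_score_matches_frozen_rho_finite_difference(self, random_setup):
        s, spec, theta, state, X, Xp, R = random_setup
        Rinv = np.linalg.inv(R)
        g = gee_score_dispersion(state, Xp, Rinv)
        eps = 1e-6
        for i in range(Xp.shape[1]):
            bp_p, bp_m = theta.beta_prime.copy(), theta.beta_prime.copy()
            bp_p[i] += eps
            bp_m[i] -= eps
            lp = loglike(s, spec, ThetaParams(theta.beta, bp_p, theta.rho), AR1)
            lm = loglike(s, spec, ThetaParams(theta.beta, bp_m, theta.rho), AR1)
            assert g[i] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5, abs=1e-6)

    def test_hessian_blocks_match_frozen_rho_finite_differences(self, random_setup):
        s, spec, theta, state, X, Xp, R = random_setup
        Rinv = np.linalg.inv(R)
        H = gee_hessian_blocks(state, X, Xp, Rinv)
        j, jp = X.shape[1], Xp.shape[1]
        D = X * state.mu[:, None]
        Sigma = np.diag(state.sd_ext) @ R @ np.diag(state.sd_ext)
        np.testing.assert_allclose(
            H[:j, :j], -D.T @ np.linalg.inv(Sigma) @ D, rtol=1e-8
        )
        eps = 1e-6
        for i in range(jp):
            bp_p, bp_m = theta.beta_prime.copy(), theta.beta_prime.copy()
            bp_p[i] += eps
            bp_m[i] -= eps
            st_p = evaluate_model(s, spec, ThetaParams(theta.beta, bp_p, theta.rho))
            st_m = evaluate_model(s, spec, ThetaParams(theta.beta, bp_m, theta.rho))
            fd_pp = (
                gee_score_dispersion(st_p, Xp, Rinv) - gee_score_dispersion(st_m, Xp, Rinv)
            ) / (2 * eps)
            np.testing.assert_allclose(H[j:, j:][:, i], fd_pp, rtol=1e-4, atol=1e-6)
            Sig_p = np.diag(st_p.sd_ext) @ R @ np.diag(st_p.sd_ext)
            Sig_m = np.diag(st_m.sd_ext) @ R @ np.diag(st_m.sd_ext)
            fd_bp = (gee_score_beta(st_p, X, Sig_p) - gee_score_beta(st_m, X, Sig_m)) / (2 * eps)
            np.testing.assert_allclose(H[:j, j:][:, i], fd_bp, rtol=1e-4, atol=1e-6)
        # symmetry of the assembled matrix by construction
        np.testing.assert_array_equal(H[j:, :j], H[:j, j:].T)

    def test_zero_stde_zeroes_dispersion_hessian(self, random_setup):
        s, spec, theta, state, X, Xp, R = random_setup
        state.stde = np.zeros(s.n)
        H = gee_hessian_blocks(state, X, Xp, np.linalg.inv(R))
        j = X.shape[1]
        np.testing.assert_allclose(H[j:, j:], 0.0, atol=1e-12)


class TestFitStandard:
    def test_intercept_only_closed_form(self, small_series):
        fit = fit_gee(small_series, PowerSpec(), IND, mode="standard")
        assert fit.theta.beta[0] == pytest.approx(np.log(np.mean(small_series.counts)), abs=1e-7)

    @pytest.mark.parametrize("with_offsets", [False, True])
    def test_ind_matches_poisson_glm(self, with_offsets):
        sim = SimSpec(
            n=60, mean_powers=(0.5,), beta=(0.3, 0.15), beta_prime=(0.2,),
            totals=2.5 if with_offsets else None, seed=5,
        )
        s, _ = simulate_series(sim)
        spec = PowerSpec(mean_powers=(0.5,))
        fit = fit_gee(s, spec, IND, mode="standard")
        X = mean_design(s, spec)
        glm = sm.GLM(
            s.counts, X, family=sm.families.Poisson(), offset=s.offsets
        ).fit()
        np.testing.assert_allclose(fit.theta.beta, glm.params, atol=1e-8)
        # phi0 matches the bias-adjusted Pearson statistic from the GLM fit
        pe2 = (s.counts - glm.mu) ** 2 / glm.mu
        assert fit.phi0 == pytest.approx(np.sum(pe2) / (s.n - 2), rel=1e-6)

    def test_phi0_scale_invariance_of_beta(self, ar1_series):
        # the constant dispersion scales the score; IND beta is unaffected
        fit = fit_gee(ar1_series, PowerSpec(mean_powers=(0.5,)), IND, mode="standard")
        X = mean_design(ar1_series, PowerSpec(mean_powers=(0.5,)))
        state = evaluate_model(ar1_series, fit.spec, fit.theta)
        np.testing.assert_allclose(X.T @ state.resid, 0.0, atol=1e-5)


class TestFitExtended:
    def test_stationarity_and_moment_rho_consistency(self, ar1_series):
        spec = PowerSpec(mean_powers=(0.5,))
        fit = fit_gee(ar1_series, spec, AR1, mode="extended")
        assert fit.converged
        assert fit.max_grad < 1e-6
        state = evaluate_model(ar1_series, fit.spec, fit.theta)
        assert fit.rho == pytest.approx(
            moment_rho(state.stde, ar1_series.times, AR1, spec.n_mean)
        )

    def test_recovers_simulation_truth_roughly(self):
        # short recovery sweep; the full-scale calibration lives in the
        # acceptance suite
        ests = []
        for seed in range(15):
            s, _ = simulate_series(
                SimSpec(
                    n=200, mean_powers=(0.5,), beta=(0.5, 0.08), beta_prime=(0.5,),
                    structure=AR1, rho=0.5, seed=seed,
                )
            )
            f = fit_gee(s, PowerSpec(mean_powers=(0.5,)), AR1, mode="extended")
            ests.append(np.r_[f.theta.beta, f.theta.beta_prime, f.rho])
        m = np.mean(ests, axis=0)
        assert m[1] == pytest.approx(0.08, abs=0.02)
        assert 0.3 < m[3] < 0.6

    def test_mode_validation(self, small_series):
        with pytest.raises(ValueError):
            fit_gee(small_series, PowerSpec(), IND, mode="bogus")
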