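"""Validation of every Gibbs/Metropolis conditional against oracles.

The conditionals are the central correctness risk of the sampler, so each
one is checked against an independent route: grid-normalized conditionals
computed from the augmented log-posterior, closed-form conjugate results,
a 2-D grid posterior for the Metropolis block, and a joint-vs-successive
(Geweke-style) simulation of the whole scan.
"""

import numpy as np
import pytest
from scipy.stats import invgamma, kstest, norm

from bsnreg.augmented import ModelState, RegressionData, augmented_loglik
from bsnreg.hyperparams import Hyperparameters, log_rho_prior, log_scaled_inv_chi2
from bsnreg.kernels import (
    brr_update_sigma2_e,
    gibbs_update_beta,
    gibbs_update_beta0,
    gibbs_update_sigma2_b,
    gibbs_update_z,
    metropolis_update_rho_sigma,
    reference_bsn_scan,
)
from bsnreg.skewnormal import logdsn_centered, CenteredParams


def _fixed_state(rng, n, p, rho=0.6):
    return ModelState(
        beta0=0.4, beta=rng.normal(size=p) * 0.5, sigma2_e=1.8, sigma2_b=0.7,
        rho=rho, z=np.abs(rng.normal(size=n)) + 0.05,
    )


def _grid_moments(grid, logdens):
    w = np.exp(logdens - logdens.max())
    w /= w.sum()
    mean = np.sum(grid * w)
    var = np.sum((grid - mean) ** 2 * w)
    return mean, var


class TestBeta0Conditional:
    def test_grid_oracle(self, rng):
        X = rng.normal(size=(3, 2))
        data = RegressionData(np.array([1.0, -0.5, 2.0]), X)
        hp = Hyperparameters(sigma2_b0=2.0)
        st = _fixed_state(rng, 3, 2)
        grid = np.linspace(-6, 8, 4001)
        logdens = np.empty_like(grid)
        for k, b0 in enumerate(grid):
            probe = ModelState(b0, st.beta, st.sigma2_e, st.sigma2_b, st.rho, z=st.z)
            logdens[k] = augmented_loglik(data, probe) - 0.5 * b0**2 / hp.sigma2_b0
        g_mean, g_var = _grid_moments(grid, logdens)
        draws = np.array([gibbs_update_beta0(data, st, hp, rng) for _ in range(20_000)])
        assert draws.mean() == pytest.approx(g_mean, abs=4 * np.sqrt(g_var / draws.size))
        assert draws.var() == pytest.approx(g_var, rel=0.05)

    def test_flat_prior_gaussian_limit(self, rng):
        # rho = 0, huge prior variance: conditional mean -> mean(y - X beta)
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        data = RegressionData(y, X)
        hp = Hyperparameters(sigma2_b0=1e12)
        st = _fixed_state(rng, 50, 3, rho=0.0)
        draws = np.array([gibbs_update_beta0(data, st, hp, rng) for _ in range(5_000)])
        target = np.mean(y - X @ st.beta)
        se = np.sqrt(st.sigma2_e / 50 / 5_000)
        assert draws.mean() == pytest.approx(target, abs=5 * se)

    def test_default_prior_negligible_shrinkage(self, rng):
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40) + 3.0
        data = RegressionData(y, X)
        st = _fixed_state(rng, 40, 2, rho=0.0)
        flat = Hyperparameters(sigma2_b0=1e12)
        dflt = Hyperparameters(sigma2_b0=1e6)
        m_flat = np.mean([gibbs_update_beta0(data, st, flat, rng) for _ in range(4_000)])
        m_dflt = np.mean([gibbs_update_beta0(data, st, dflt, rng) for _ in range(4_000)])
        assert abs(m_flat - m_dflt) / abs(m_flat) < 1e-2


class TestBetaConditional:
    def test_single_predictor_conjugate(self, rng):
        # p=1, rho=0: the textbook Bayesian simple-regression conditional
        x = rng.normal(size=30)
        y = 2.0 * x + rng.normal(size=30)
        data = RegressionData(y, x[:, None])
        st = _fixed_state(rng, 30, 1, rho=0.0)
        hp = Hyperparameters()
        prec = 1.0 / st.sigma2_e
        d1 = prec * np.sum(x**2) + 1.0 / st.sigma2_b
        c1 = prec * np.sum(x * (y - st.beta0))
        draws = np.array([gibbs_update_beta(data, st, hp, rng)[0] for _ in range(20_000)])
        assert draws.mean() == pytest.approx(c1 / d1, abs=5 / np.sqrt(d1 * draws.size))
        assert draws.var() == pytest.approx(1.0 / d1, rel=0.05)

    def test_sweep_stationary_distribution_matches_joint(self, rng):
        # n=4, p=2: iterate sweeps; stationary law is the exact bivariate
        # normal conditional computed by linear algebra
        X = np.array([[1.0, 0.5], [0.0, 1.0], [1.0, 1.0], [0.5, 0.0]])
        y = np.array([1.0, 0.3, -0.2, 0.8])
        data = RegressionData(y, X)
        st = _fixed_state(rng, 4, 2, rho=0.7)
        hp = Hyperparameters()
        from bsnreg.augmented import _shift_constants

        zeta, c, d = _shift_constants(st.rho, st.sigma2_e)
        w = y - c * st.z + d - st.beta0
        P = zeta**2 * X.T @ X + np.eye(2) / st.sigma2_b
        mean = np.linalg.solve(P, zeta**2 * X.T @ w)
        cov = np.linalg.inv(P)
        draws = np.empty((30_000, 2))
        for k in range(draws.shape[0]):
            st.beta = gibbs_update_beta(data, st, hp, rng)
            draws[k] = st.beta
        err = 5 * np.sqrt(np.diag(cov) / draws.shape[0]) * 3  # autocorrelation margin
        np.testing.assert_allclose(draws.mean(axis=0), mean, atol=err.max())
        np.testing.assert_allclose(np.cov(draws.T), cov, rtol=0.1, atol=0.01)

    def test_strong_shrinkage_limit(self, rng):
        X = rng.normal(size=(20, 3))
        data = RegressionData(rng.normal(size=20), X)
        st = _fixed_state(rng, 20, 3)
        st.sigma2_b = 1e-8
        hp = Hyperparameters()
        beta = gibbs_update_beta(data, st, hp, rng)
        assert np.all(np.abs(beta) < 1e-2)


class TestVarianceConditionals:
    def test_sigma2_b_prior_posterior_match(self, rng):
        # beta = 0: the conditional collapses to ScaledInvChi2(df_b + p, S_b)
        st = _fixed_state(rng, 5, 3)
        st.beta = np.zeros(3)
        hp = Hyperparameters(S_b=2.0, df_b=4.0)
        draws = np.array([gibbs_update_sigma2_b(st, hp, rng) for _ in range(5_000)])
        assert np.all(draws > 0)
        dof = hp.df_b + 3
        assert kstest(draws, invgamma(dof / 2, scale=hp.S_b / 2).cdf).pvalue > 0.01

    def test_sigma2_b_long_run_mean(self, rng):
        st = _fixed_state(rng, 5, 4)
        hp = Hyperparameters(S_b=1.5, df_b=6.0)
        draws = np.array([gibbs_update_sigma2_b(st, hp, rng) for _ in range(40_000)])
        dof = hp.df_b + 4
        expected = (hp.S_b + st.beta @ st.beta) / (dof - 2.0)
        assert draws.mean() == pytest.approx(expected, rel=0.03)

    def test_brr_sigma2_e_grid_oracle(self, rng):
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        data = RegressionData(y, X)
        st = _fixed_state(rng, 6, 2, rho=0.0)
        hp = Hyperparameters()
        e = y - st.beta0 - X @ st.beta
        dof = hp.df_e + 6
        scale = hp.S_e + e @ e
        draws = np.array([brr_update_sigma2_e(data, st, hp, rng) for _ in range(5_000)])
        assert kstest(draws, invgamma(dof / 2, scale=scale / 2).cdf).pvalue > 0.01


class TestLatentConditional:
    def test_rho_zero_half_normal(self, rng):
        X = rng.normal(size=(2_000, 2))
        data = RegressionData(rng.normal(size=2_000), X)
        st = _fixed_state(rng, 2_000, 2, rho=0.0)
        z = gibbs_update_z(data, st, rng)
        assert np.all(z > 0)
        expected = np.sqrt(2 / np.pi)
        se = np.sqrt((1 - 2 / np.pi) / 2_000)
        assert z.mean() == pytest.approx(expected, abs=4 * se)

    def test_single_observation_distribution(self, rng):
        from bsnreg.augmented import z_conditional_params

        X = np.array([[1.0], [0.0]])
        y = np.array([2.0, 0.0])
        data = RegressionData(y, X)
        st = _fixed_state(rng, 2, 1, rho=0.8)
        m, v = z_conditional_params(y[0], st.beta0 + st.beta[0], st.rho, st.sigma2_e)
        draws = np.array([gibbs_update_z(data, st, rng)[0] for _ in range(5_000)])
        sd = np.sqrt(v)
        tn_cdf = lambda x: (norm.cdf(x, m, sd) - norm.cdf(0, m, sd)) / norm.sf(0, m, sd)
        assert kstest(draws, tn_cdf).pvalue > 0.01


class TestMetropolisBlock:
    def test_degenerate_proposal_always_accepted(self, rng):
        X = rng.normal(size=(10, 2))
        data = RegressionData(rng.normal(size=10), X)
        st = _fixed_state(rng, 10, 2)
        hp = Hyperparameters()
        for _ in range(50):
            _, _, acc_r, acc_s = metropolis_update_rho_sigma(
                data, st, hp, rng, rho_step=1e-14, sig_step=1e-14
            )
            assert acc_r and acc_s

    def test_grid_posterior_oracle(self, rng):
        # location parameters fixed at truth; chain over (z, rho, sigma2_e)
        # must reproduce the 2-D grid posterior computed from the marginal
        # likelihood (z integrated analytically)
        n = 40
        from bsnreg.simulate import SimulationSettings, simulate_phenotypes

        X = np.zeros((n, 1))
        settings = SimulationSettings(
            n=n, p=1, rho_true=0.9, n_replicates=1, seed=5, effect_indices=(1,),
            effect_variance=1e-12,
        )
        y, _ = simulate_phenotypes(X, settings, replicate_seed=17)
        data = RegressionData(y, X)
        hp = Hyperparameters(S_e=3.5, df_e=5.0)
        st = ModelState(beta0=3.0, beta=np.zeros(1), sigma2_e=1.5, sigma2_b=1.0,
                        rho=0.0, z=np.full(n, 0.8))

        rho_grid = np.linspace(-0.985, 0.985, 120)
        s2_grid = np.exp(np.linspace(np.log(0.5), np.log(8.0), 90))
        resid = y - 3.0
        logpost = np.empty((rho_grid.size, s2_grid.size))
        for i, r in enumerate(rho_grid):
            for j, s2 in enumerate(s2_grid):
                cp = CenteredParams(0.0, s2, r)
                logpost[i, j] = (
                    np.sum(logdsn_centered(resid, cp))
                    + log_rho_prior(r, hp.a0, hp.b0)
                    + log_scaled_inv_chi2(s2, hp.df_e, hp.S_e)
                    + np.log(s2)  # log-spaced s2 grid Jacobian
                )
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        grid_rho_mean = np.sum(w.sum(axis=1) * rho_grid)
        grid_s2_mean = np.sum(w.sum(axis=0) * s2_grid)

        n_iter, burn = 24_000, 4_000
        rhos = np.empty(n_iter - burn)
        s2s = np.empty(n_iter - burn)
        for it in range(n_iter):
            st.z = gibbs_update_z(data, st, rng)
            rho, s2, _, _ = metropolis_update_rho_sigma(
                data, st, hp, rng, rho_step=0.35, sig_step=0.35
            )
            st.rho, st.sigma2_e = rho, s2
            if it >= burn:
                rhos[it - burn] = rho
                s2s[it - burn] = s2
        assert rhos.mean() == pytest.approx(grid_rho_mean, abs=0.05)
        assert s2s.mean() == pytest.approx(grid_s2_mean, rel=0.08)


class TestGewekeJointVsSuccessive:
    """Joint simulation vs successive-conditional simulation of the scan.

    If every conditional is correct, cycling {parameter scan, data redraw}
    leaves the joint prior-predictive distribution invariant, so the
    parameter marginals from the chain must match direct prior draws.
    """

    def test_first_two_moments_agree(self, rng):
        n, p = 3, 2
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        hp = Hyperparameters(sigma2_b0=1.0, df_e=9.0, S_e=7.0, df_b=9.0, S_b=7.0,
                             a0=2.0, b0=2.0)

        def prior_draw():
            b0 = rng.normal(0, 1.0)
            s2b = (hp.S_b / rng.chisquare(hp.df_b))
            beta = rng.normal(0, np.sqrt(s2b), size=p)
            s2e = hp.S_e / rng.chisquare(hp.df_e)
            rho = 1.0 - 2.0 * rng.beta(hp.a0, hp.b0)
            z = np.abs(rng.normal(size=n))
            return ModelState(b0, beta, s2e, s2b, rho, z=z)

        def draw_y(st):
            from bsnreg.augmented import _shift_constants

            zeta, c, d = _shift_constants(st.rho, st.sigma2_e)
            mu = st.beta0 + X @ st.beta
            return mu + c * st.z - d + rng.normal(size=n) / zeta

        n_joint = 20_000
        joint = np.empty((n_joint, 3))
        for k in range(n_joint):
            st = prior_draw()
            joint[k] = (st.beta0, st.sigma2_e, st.rho)

        n_chain, thin = 30_000, 1
        st = prior_draw()
        succ = np.empty((n_chain, 3))
        for k in range(n_chain):
            y = draw_y(st)
            data = RegressionData(y, X)
            reference_bsn_scan(data, st, hp, rng, rho_step=0.8, sig_step=0.8)
            succ[k] = (st.beta0, st.sigma2_e, st.rho)

        for idx, (scale, rel) in enumerate([(1.0, None), (None, 0.12), (0.577, None)]):
            jm, sm = joint[:, idx].mean(), succ[:, idx].mean()
            js, ss_ = joint[:, idx].std(), succ[:, idx].std()
            if rel is None:
                assert abs(jm - sm) < 0.12 * scale
                assert abs(js - ss_) < 0.20 * scale
            else:
                assert abs(jm - sm) / jm < rel
                assert abs(js - ss_) / js < 0.25
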