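"""Reference MCMC update kernels, one function per full conditional.

These are straightforward numpy implementations of every Gibbs and
Metropolis update used by the samplers, written for clarity and testability:
each one is validated against grid / quadrature oracles and a
joint-vs-successive-conditional (Geweke-style) check in the test suite.
The production sampler in ``_fast`` fuses the same updates into a single
numba-compiled chain; the two paths are compared distributionally.

Conditional structure (derived by completing squares in the augmented
posterior; see docs/derivations.md):

given the latent z the skew-normal regression is a Gaussian regression in
the working response ``w = y - c z + d`` with homoscedastic precision
``zeta^2``, so beta0, beta and sigma2_b have conjugate updates identical in
form to Bayesian ridge regression; each z_i is truncated normal; and
(rho, sigma2_e) jointly lack closed-form conditionals and are updated by
univariate random-walk Metropolis on transformed scales (atanh and log).
"""

from __future__ import annotations

import numpy as np

from .augmented import (
    ModelState,
    RegressionData,
    _shift_constants,
    sample_truncated_normal,
    z_conditional_params,
)
from .hyperparams import (
    Hyperparameters,
    log_rho_prior,
    log_scaled_inv_chi2,
    sample_scaled_inv_chi2,
)

__all__ = [
    "gibbs_update_beta0",
    "gibbs_update_beta",
    "gibbs_update_sigma2_b",
    "gibbs_update_z",
    "metropolis_update_rho_sigma",
    "brr_update_sigma2_e",
]


def _working_response(data: RegressionData, state: ModelState) -> tuple[np.ndarray, float]:
    """(w, precision): Gaussianised response and its homoscedastic precision."""
    zeta, c, d = _shift_constants(state.rho, state.sigma2_e)
    return data.y - c * state.z + d, zeta**2


def gibbs_update_beta0(
    data: RegressionData, state: ModelState, hp: Hyperparameters,
    rng: np.random.Generator,
) -> float:
    """Draw beta0 | rest ~ N(mean, var).

    Precision n*prec + 1/sigma2_b0; mean is the precision-weighted average of
    the working residuals w_i - x_i' beta.
    """
    w, prec = _working_response(data, state)
    resid = w - data.X @ state.beta
    post_prec = data.n * prec + 1.0 / hp.sigma2_b0
    post_mean = prec * np.sum(resid) / post_prec
    return float(post_mean + rng.standard_normal() / np.sqrt(post_prec))


def gibbs_update_beta(
    data: RegressionData, state: ModelState, hp: Hyperparameters,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single-site Gibbs sweep over marker effects, ascending j.

    beta_j | rest ~ N(c_j/d_j, 1/d_j) with d_j = prec * sum_i x_ij^2 +
    1/sigma2_b and c_j = prec * sum_i x_ij * (partial residual excluding j).
    """
    w, prec = _working_response(data, state)
    beta = state.beta.copy()
    r = w - state.beta0 - data.X @ beta
    ss = np.einsum("ij,ij->j", data.X, data.X)
    for j in range(data.p):
        xj = data.X[:, j]
        cj = prec * (xj @ r + ss[j] * beta[j])
        dj = prec * ss[j] + 1.0 / state.sigma2_b
        new = cj / dj + rng.standard_normal() / np.sqrt(dj)
        r -= xj * (new - beta[j])
        beta[j] = new
    return beta


def gibbs_update_sigma2_b(
    state: ModelState, hp: Hyperparameters, rng: np.random.Generator
) -> float:
    """sigma2_b | rest ~ ScaledInvChi2(df_b + p, S_b + beta'beta)."""
    return sample_scaled_inv_chi2(
        hp.df_b + state.beta.size, hp.S_b + float(np.dot(state.beta, state.beta)), rng
    )


def gibbs_update_z(
    data: RegressionData, state: ModelState, rng: np.random.Generator
) -> np.ndarray:
    """Draw each z_i independently from its truncated-normal conditional."""
    mu = state.mean(data.X)
    m, v = z_conditional_params(data.y, mu, state.rho, state.sigma2_e)
    return np.asarray(sample_truncated_normal(m, v, seed=rng), dtype=float)


def _augmented_ll_rho_sigma(
    resid: np.ndarray, z: np.ndarray, rho: float, sigma2_e: float
) -> float:
    """Terms of the augmented log-likelihood that involve (rho, sigma2_e).

    resid = y - beta0 - X beta.  The z half-normal terms are constant here.
    """
    zeta, c, d = _shift_constants(rho, sigma2_e)
    r = resid - c * z + d
    return float(resid.size * np.log(zeta) - 0.5 * zeta**2 * np.dot(r, r))


def metropolis_update_rho_sigma(
    data: RegressionData,
    state: ModelState,
    hp: Hyperparameters,
    rng: np.random.Generator,
    rho_step: float = 0.1,
    sig_step: float = 0.1,
) -> tuple[float, float, bool, bool]:
    """Two univariate random-walk Metropolis steps for rho and sigma2_e.

    rho walks on the atanh scale and sigma2_e on the log scale; the
    log-Jacobians log(1 - rho^2) and log(sigma2_e) enter the acceptance
    ratio so the targets remain the conditionals on the natural scales.
    Returns (rho, sigma2_e, accepted_rho, accepted_sigma).
    """
    resid = data.y - state.mean(data.X)
    rho, s2 = state.rho, state.sigma2_e

    def logpost(r_, s2_):
        return (
            _augmented_ll_rho_sigma(resid, state.z, r_, s2_)
            + log_rho_prior(r_, hp.a0, hp.b0)
            + log_scaled_inv_chi2(s2_, hp.df_e, hp.S_e)
        )

    lp = logpost(rho, s2)

    t_prop = np.arctanh(rho) + rho_step * rng.standard_normal()
    rho_prop = np.tanh(t_prop)
    lp_prop = logpost(rho_prop, s2)
    log_ratio = (lp_prop + np.log1p(-rho_prop**2)) - (lp + np.log1p(-rho**2))
    acc_rho = np.log(rng.uniform()) < log_ratio
    if acc_rho:
        rho, lp = float(rho_prop), lp_prop

    s2_prop = s2 * np.exp(sig_step * rng.standard_normal())
    lp_prop = logpost(rho, s2_prop)
    log_ratio = (lp_prop + np.log(s2_prop)) - (lp + np.log(s2))
    acc_sig = np.log(rng.uniform()) < log_ratio
    if acc_sig:
        s2 = float(s2_prop)

    return rho, s2, bool(acc_rho), bool(acc_sig)


def reference_bsn_scan(
    data: RegressionData,
    state: ModelState,
    hp: Hyperparameters,
    rng: np.random.Generator,
    rho_step: float = 0.1,
    sig_step: float = 0.1,
    fix_rho: bool = False,
) -> tuple[bool, bool]:
    """One full sampler scan {beta0, beta, sigma2_b, z, (rho, sigma2_e)-MH}.

    Mutates ``state`` in place; returns the two Metropolis acceptance flags.
    Used by the reference sampler path and the Geweke-style validation.
    """
    state.beta0 = gibbs_update_beta0(data, state, hp, rng)
    state.beta = gibbs_update_beta(data, state, hp, rng)
    state.sigma2_b = gibbs_update_sigma2_b(state, hp, rng)
    state.z = gibbs_update_z(data, state, rng)
    if fix_rho:
        resid = data.y - state.mean(data.X)
        s2_prop = state.sigma2_e * np.exp(sig_step * rng.standard_normal())
        lp = (
            _augmented_ll_rho_sigma(resid, state.z, state.rho, state.sigma2_e)
            + log_scaled_inv_chi2(state.sigma2_e, hp.df_e, hp.S_e)
            + np.log(state.sigma2_e)
        )
        lp_prop = (
            _augmented_ll_rho_sigma(resid, state.z, state.rho, s2_prop)
            + log_scaled_inv_chi2(s2_prop, hp.df_e, hp.S_e)
            + np.log(s2_prop)
        )
        acc = np.log(rng.uniform()) < lp_prop - lp
        if acc:
            state.sigma2_e = float(s2_prop)
        return False, bool(acc)
    rho, s2, acc_rho, acc_sig = metropolis_update_rho_sigma(
        data, state, hp, rng, rho_step=rho_step, sig_step=sig_step
    )
    state.rho, state.sigma2_e = rho, s2
    return acc_rho, acc_sig


def reference_brr_scan(
    data: RegressionData,
    state: ModelState,
    hp: Hyperparameters,
    rng: np.random.Generator,
) -> None:
    """One all-Gibbs scan of the Gaussian-error (ridge) model.

    ``state`` must carry rho = 0 and a (dummy) positive z so the shared
    location updates reduce to their Gaussian form.
    """
    state.beta0 = gibbs_update_beta0(data, state, hp, rng)
    state.beta = gibbs_update_beta(data, state, hp, rng)
    state.sigma2_b = gibbs_update_sigma2_b(state, hp, rng)
    state.sigma2_e = brr_update_sigma2_e(data, state, hp, rng)


def brr_update_sigma2_e(
    data: RegressionData, state: ModelState, hp: Hyperparameters,
    rng: np.random.Generator,
) -> float:
    """Conjugate residual-variance update of the Gaussian (ridge) model.

    sigma2_e | rest ~ ScaledInvChi2(df_e + n, S_e + e'e).
    """
    e = data.y - state.mean(data.X)
    return sample_scaled_inv_chi2(hp.df_e + data.n, hp.S_e + float(np.dot(e, e)), rng)
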