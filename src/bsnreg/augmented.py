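"""Augmented (Y, Z) model for skew-normal regression.

A centered skew-normal observation Y ~ SN_C(mu, sigma2_e, gamma1(rho)) admits
the stochastic representation

    Y = mu + sigma_e * (U - EU) / SU,     U | Z = z ~ N(rho z, 1 - rho^2),
    Z ~ TN(0, 1, 0, inf)   (half-normal),

so the joint density of (Y, Z) is

    f(y, z) = zeta/sqrt(2 pi) exp{-zeta^2/2 (y - mu - c z + d)^2}
              * 2/sqrt(2 pi) exp{-z^2/2} 1(z > 0),

with EU = sqrt(2/pi) rho, SU = sqrt(1 - (2/pi) rho^2),
zeta = SU / (sigma_e sqrt(1 - rho^2)), c = sigma_e rho / SU and
d = sigma_e EU / SU.  Integrating z out recovers the SN_C density, which is
what makes Gibbs sampling with the latent z tractable: given z the model is
an ordinary Gaussian regression in the working response y - c z + d with
precision zeta^2, and given everything else each z_i is truncated normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, truncnorm

from .skewnormal import CenteredParams, logdsn_centered, sn_constants

__all__ = [
    "RegressionData",
    "ModelState",
    "ZetaConstants",
    "zeta_constants",
    "augmented_loglik",
    "marginalized_loglik",
    "z_conditional_params",
    "sample_truncated_normal",
]

_LOG_PI = float(np.log(np.pi))


@dataclass(frozen=True)
class RegressionData:
    """Phenotype vector y (length n) and marker matrix X (n x p)."""

    y: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        X = np.asarray(self.X, dtype=float)
        if y.ndim != 1 or X.ndim != 2:
            raise ValueError("y must be 1-D and X 2-D")
        if X.shape[0] != y.size:
            raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} entries")
        if y.size < 2 or X.shape[1] < 1:
            raise ValueError("need n >= 2 observations and p >= 1 markers")
        if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
            raise ValueError("missing or non-finite values are not supported")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class ModelState:
    """One MCMC state of the skew-normal regression model."""

    beta0: float
    beta: np.ndarray
    sigma2_e: float
    sigma2_b: float
    rho: float
    z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.sigma2_e <= 0 or self.sigma2_b <= 0:
            raise ValueError("variances must be strictly positive")
        if not abs(self.rho) < 1:
            raise ValueError(f"rho must lie in (-1, 1), got {self.rho}")
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)

    def mean(self, X: np.ndarray) -> np.ndarray:
        return self.beta0 + X @ self.beta


@dataclass(frozen=True)
class ZetaConstants:
    """Constants of the augmented density at (rho, sigma2_e)."""

    EU: float
    SU: float
    zeta: float


def zeta_constants(rho: float, sigma2_e: float) -> ZetaConstants:
    """EU, SU and zeta = SU / (sigma_e * sqrt(1 - rho^2))."""
    if not abs(rho) < 1:
        raise ValueError(f"rho must lie in (-1, 1), got {rho}")
    if sigma2_e <= 0:
        raise ValueError(f"sigma2_e must be positive, got {sigma2_e}")
    k = sn_constants(rho)
    zeta = k.SU / (np.sqrt(sigma2_e) * np.sqrt(1.0 - rho * rho))
    return ZetaConstants(EU=k.EU, SU=k.SU, zeta=float(zeta))


def _shift_constants(rho: float, sigma2_e: float) -> tuple[float, float, float]:
    """(zeta, c, d) with c = sigma_e*rho/SU and d = sigma_e*EU/SU."""
    k = zeta_constants(rho, sigma2_e)
    sigma_e = np.sqrt(sigma2_e)
    return k.zeta, float(sigma_e * rho / k.SU), float(sigma_e * k.EU / k.SU)


def augmented_loglik(data: RegressionData, state: ModelState) -> float:
    """Complete-data log-likelihood of (y, z) at the given state.

    Sum over observations of
    ``log zeta - log pi - zeta^2/2 (y_i - mu_i - c z_i + d)^2 - z_i^2/2``;
    the normalising constants are carried exactly so the value is on the
    same scale as :func:`marginalized_loglik`.  Returns -inf if any z_i <= 0.
    """
    if state.z is None or state.z.size != data.n:
        raise ValueError("state.z must be a length-n latent vector")
    if state.beta.size != data.p:
        raise ValueError("state.beta length must match number of markers")
    if np.any(state.z <= 0):
        return -np.inf
    zeta, c, d = _shift_constants(state.rho, state.sigma2_e)
    r = data.y - state.mean(data.X) - c * state.z + d
    return float(
        data.n * (np.log(zeta) - _LOG_PI)
        - 0.5 * zeta**2 * np.dot(r, r)
        - 0.5 * np.dot(state.z, state.z)
    )


def marginalized_loglik(data: RegressionData, state: ModelState) -> float:
    """Observed-data log-likelihood with z integrated out.

    Sum of centered skew-normal log densities SN_C(y_i | mu_i, sigma2_e,
    gamma1(rho)); the quantity entering the deviance and DIC.
    """
    if state.beta.size != data.p:
        raise ValueError("state.beta length must match number of markers")
    resid = data.y - state.mean(data.X)
    cp = CenteredParams(mu=0.0, sigma2_e=state.sigma2_e, rho=state.rho)
    return float(np.sum(logdsn_centered(resid, cp)))


def z_conditional_params(yi, mu_i, rho: float, sigma2_e: float):
    """Parameters (m, v) of the full conditional z_i | y_i, rest.

    Completing the square in z_i in the augmented density gives a normal
    with variance v = 1 / (1 + zeta^2 c^2) truncated to (0, inf) and mean
    m = v * zeta^2 * c * (y_i - mu_i + d), where c = sigma_e rho / SU and
    d = sigma_e EU / SU.  At rho = 0 this is the half-normal (m=0, v=1).
    Accepts scalars or arrays for ``yi`` and ``mu_i``.
    """
    zeta, c, d = _shift_constants(rho, sigma2_e)
    v = 1.0 / (1.0 + zeta**2 * c**2)
    a = np.asarray(yi, dtype=float) - np.asarray(mu_i, dtype=float) + d
    m = v * zeta**2 * c * a
    if np.ndim(m) == 0:
        return float(m), float(v)
    return m, float(v)


def sample_truncated_normal(m, v, seed=None, size=None):
    """Draw from N(m, v) conditioned on (0, inf).

    Numerically stable for means far below zero (scipy's truncnorm uses
    tail-accurate inverse CDFs).  ``m`` may be an array; draws are taken
    element-wise.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("variance must be strictly positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = np.sqrt(v)
    a = (0.0 - np.asarray(m, dtype=float)) / sd
    draw = truncnorm.rvs(a, np.inf, loc=m, scale=sd, size=size, random_state=rng)
    return draw


def truncated_normal_mean(m: float, v: float) -> float:
    """Mean of N(m, v) truncated to (0, inf) (closed form, for oracles)."""
    sd = np.sqrt(v)
    alpha = -m / sd
    return float(m + sd * norm.pdf(alpha) / norm.sf(alpha))
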