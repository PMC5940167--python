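"""Skew-normal distribution theory.

The skew-normal (SN) law generalises the normal distribution with a shape
parameter controlling asymmetry.  Two parametrizations are used throughout:

* **direct**: location ``xi``, scale ``omega > 0``, shape ``lam``; the
  standard density is ``f(u | lam) = 2 phi(u) Phi(lam * u)``.
* **centered**: mean ``mu``, variance ``sigma2_e``, and shape ``rho`` in
  (-1, 1) (equivalently the skewness coefficient ``gamma1``).  The centered
  form is preferred for estimation because its parameters are interpretable
  moments of the observable.

The two are linked through the *hidden truncation* construction: if (V, W)
is bivariate standard normal with correlation ``rho`` then W | V > 0 is
skew-normal with ``lam = rho / sqrt(1 - rho**2)``.  This construction is
also the basis of the data augmentation used by the MCMC samplers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr
from scipy.stats import norm

__all__ = [
    "GAMMA1_MAX",
    "DirectParams",
    "CenteredParams",
    "DerivedConstants",
    "dsn_direct",
    "logdsn_direct",
    "moments_direct",
    "rho_to_lambda",
    "lambda_to_rho",
    "rho_to_gamma1",
    "gamma1_to_rho",
    "centered_to_direct",
    "dsn_centered",
    "logdsn_centered",
    "sn_constants",
    "rsn_hidden_truncation",
    "sample_skewness",
]

_SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi)

#: Supremum of |gamma1| attainable by a skew-normal law (the |rho| -> 1 limit).
GAMMA1_MAX = float(
    _SQRT_2_OVER_PI * (4.0 / np.pi - 1.0) * (1.0 - 2.0 / np.pi) ** -1.5
)


@dataclass(frozen=True)
class DirectParams:
    """Direct parametrization SN_D(xi, omega, lam)."""

    xi: float = 0.0
    omega: float = 1.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.xi) and np.isfinite(self.omega) and np.isfinite(self.lam)):
            raise ValueError("direct parameters must be finite")
        if self.omega <= 0:
            raise ValueError(f"scale omega must be positive, got {self.omega}")


@dataclass(frozen=True)
class CenteredParams:
    """Centered parametrization SN_C(mu, sigma2_e, gamma1) indexed by rho."""

    mu: float = 0.0
    sigma2_e: float = 1.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2_e <= 0:
            raise ValueError(f"variance sigma2_e must be positive, got {self.sigma2_e}")
        if not abs(self.rho) < 1:
            raise ValueError(f"shape rho must lie in (-1, 1), got {self.rho}")

    @property
    def gamma1(self) -> float:
        """Pearson skewness coefficient implied by rho."""
        return rho_to_gamma1(self.rho)


@dataclass(frozen=True)
class DerivedConstants:
    """Mean EU and standard deviation SU of the standard SN variate at rho."""

    EU: float
    SU: float


def sn_constants(rho: float) -> DerivedConstants:
    """EU = sqrt(2/pi)*rho and SU = sqrt(1 - (2/pi)*rho^2) for shape rho."""
    if not abs(rho) <= 1:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    eu = _SQRT_2_OVER_PI * rho
    su = np.sqrt(1.0 - (2.0 / np.pi) * rho * rho)
    return DerivedConstants(EU=float(eu), SU=float(su))


def dsn_direct(u, lam):
    """Standard skew-normal density 2*phi(u)*Phi(lam*u).

    Reduces to the standard normal density when ``lam == 0``.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)) or not np.isfinite(lam):
        raise ValueError("u and lam must be finite")
    out = 2.0 * norm.pdf(u) * norm.cdf(lam * u)
    return float(out) if out.ndim == 0 else out


def logdsn_direct(u, lam):
    """Log of :func:`dsn_direct`, finite for all finite u (stable tail CDF)."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)) or not np.isfinite(lam):
        raise ValueError("u and lam must be finite")
    out = np.log(2.0) + norm.logpdf(u) + log_ndtr(lam * u)
    return float(out) if out.ndim == 0 else out


def moments_direct(lam: float) -> tuple[float, float]:
    """Mean and variance of the standard SN_D(lam) variate.

    mean = sqrt(2/pi) * lam / sqrt(1 + lam^2);
    variance = 1 - (2/pi) * lam^2 / (1 + lam^2), always in (1 - 2/pi, 1].
    """
    if not np.isfinite(lam):
        raise ValueError("lam must be finite")
    delta = lam / np.sqrt(1.0 + lam * lam)
    mean = _SQRT_2_OVER_PI * delta
    var = 1.0 - (2.0 / np.pi) * delta * delta
    return float(mean), float(var)


def rho_to_lambda(rho: float) -> float:
    """Map the hidden-truncation correlation rho to the direct shape lam."""
    if not abs(rho) < 1:
        raise ValueError(f"rho must lie in (-1, 1), got {rho}")
    return float(rho / np.sqrt(1.0 - rho * rho))


def lambda_to_rho(lam: float) -> float:
    """Inverse of :func:`rho_to_lambda`: rho = lam / sqrt(1 + lam^2)."""
    if not np.isfinite(lam):
        raise ValueError("lam must be finite")
    return float(lam / np.sqrt(1.0 + lam * lam))


def rho_to_gamma1(rho: float) -> float:
    """Skewness gamma1 = sqrt(2/pi)*rho^3*(4/pi - 1)*(1 - 2 rho^2/pi)^(-3/2).

    Odd and strictly increasing on [-1, 1]; bounded by ``GAMMA1_MAX``
    (~0.99527) in absolute value, the classic skew-normal skewness range.
    The boundary |rho| = 1 is allowed and yields the limiting value.
    """
    if not abs(rho) <= 1:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    return float(
        _SQRT_2_OVER_PI
        * rho**3
        * (4.0 / np.pi - 1.0)
        * (1.0 - 2.0 * rho * rho / np.pi) ** -1.5
    )


def gamma1_to_rho(gamma1: float) -> float:
    """Numerically invert :func:`rho_to_gamma1` (monotone bracketed root).

    |gamma1| requests at or beyond the attainable bound ``GAMMA1_MAX`` are
    rejected; values within 1e-6 of the bound are clamped before the root
    find to keep the bracket well conditioned.
    """
    if not np.isfinite(gamma1):
        raise ValueError("gamma1 must be finite")
    if abs(gamma1) >= GAMMA1_MAX:
        raise ValueError(
            f"|gamma1| must be < {GAMMA1_MAX:.5f} (skew-normal bound), got {gamma1}"
        )
    if gamma1 == 0.0:
        return 0.0
    target = np.clip(gamma1, -(GAMMA1_MAX - 1e-6), GAMMA1_MAX - 1e-6)
    root = optimize.brentq(
        lambda r: rho_to_gamma1(r) - target, -1.0, 1.0, xtol=1e-14, rtol=1e-15
    )
    return float(root)


def centered_to_direct(cp: CenteredParams) -> DirectParams:
    """Map SN_C(mu, sigma2_e, rho) to SN_D(xi, omega, lam).

    The standardised variate (U - EU)/SU has mean 0 and variance 1, so
    omega = sigma_e / SU and xi = mu - omega * EU give a direct-form law
    with mean mu and variance sigma2_e.
    """
    k = sn_constants(cp.rho)
    sigma_e = np.sqrt(cp.sigma2_e)
    omega = sigma_e / k.SU
    xi = cp.mu - omega * k.EU
    return DirectParams(xi=float(xi), omega=float(omega), lam=rho_to_lambda(cp.rho))


def dsn_centered(y, cp: CenteredParams):
    """Density of the centered-parametrization skew normal at y."""
    return np.exp(logdsn_centered(y, cp))


def logdsn_centered(y, cp: CenteredParams):
    """Log-density of SN_C(mu, sigma2_e, rho), via the direct-form map."""
    dp = centered_to_direct(cp)
    u = (np.asarray(y, dtype=float) - dp.xi) / dp.omega
    out = logdsn_direct(u, dp.lam) - np.log(dp.omega)
    return float(out) if np.ndim(out) == 0 else out


def rsn_hidden_truncation(n: int, rho: float, seed=None) -> np.ndarray:
    """Draw n standard SN variates via the hidden-truncation representation.

    Each draw takes z half-normal (|N(0,1)|, i.e. TN(0, 1, 0, inf)) and then
    u | z ~ N(rho * z, 1 - rho^2).

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if not abs(rho) < 1:
        raise ValueError(f"rho must lie in (-1, 1), got {rho}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    z = np.abs(rng.standard_normal(n))
    return rho * z + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)


def sample_skewness(y, ddof: int = 1) -> float:
    """Sample skewness index gamma1_hat = m3 / s^3.

    m3 is the third central moment with the 1/n convention; s is the sample
    standard deviation, by default with the n-1 denominator (``ddof=1``).
    Pass ``ddof=0`` for the n-denominator (biased) variant.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    s = y.std(ddof=ddof)
    if s == 0:
        raise ValueError("sample skewness undefined for a constant vector")
    m3 = np.mean((y - y.mean()) ** 3)
    return float(m3 / s**3)
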