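"""Prior specification and hyper-parameter elicitation.

Priors for the whole-genome regression (shared by the skew-normal and the
ridge models):

* ``beta0 ~ N(0, sigma2_b0)`` with a large, effectively flat variance;
* ``beta | sigma2_b ~ N_p(0, sigma2_b I)`` (the ridge-type common prior);
* ``sigma2_e ~ ScaledInvChi2(df_e, S_e)``, ``sigma2_b ~ ScaledInvChi2(df_b, S_b)``
  with density proportional to ``(s2)^-(df/2 + 1) exp(-S / (2 s2))``;
* ``rho = 1 - 2 B`` with ``B ~ Beta(a0, b0)``, hence a Beta-shaped prior on
  (-1, 1); the default a0 = b0 = 1 makes it uniform.

The scale rules follow the standard genomic-prediction elicitation that
splits the phenotypic variance evenly between signal and noise a priori:
``S_e = 0.5 * Vy * (df_e + 2)`` puts the prior mode of sigma2_e at half the
phenotypic variance, and ``S_b = 0.5 * Vy * (df_b + 2) / MSx`` does the same
for the marker-effect variance after scaling by the mean sum of squared
genotype codes ``MSx = (1/n) sum_ij x_ij^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

from .augmented import ModelState, RegressionData

__all__ = [
    "Hyperparameters",
    "default_hyperparameters",
    "log_scaled_inv_chi2",
    "sample_scaled_inv_chi2",
    "log_rho_prior",
    "log_prior",
]


@dataclass(frozen=True)
class Hyperparameters:
    sigma2_b0: float = 1e6
    df_e: float = 5.0
    S_e: float = 3.5
    df_b: float = 5.0
    S_b: float = 3.5
    a0: float = 1.0
    b0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma2_b0", "df_e", "S_e", "df_b", "S_b", "a0", "b0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyper-parameter {name} must be positive")


def default_hyperparameters(
    data: RegressionData, *, df_e: float = 5.0, df_b: float = 5.0,
    a0: float = 1.0, b0: float = 1.0,
) -> Hyperparameters:
    """Elicit prior scales from the data.

    Vy is the sample phenotypic variance (n-1 denominator); the scales put
    half of Vy on the residual and half on the markers a priori.
    """
    vy = float(np.var(data.y, ddof=1))
    if vy <= 0:
        raise ValueError("phenotype variance is zero; cannot elicit prior scales")
    msx = float(np.sum(data.X.astype(float) ** 2) / data.n)
    return Hyperparameters(
        sigma2_b0=1e6,
        df_e=df_e,
        S_e=0.5 * vy * (df_e + 2.0),
        df_b=df_b,
        S_b=0.5 * vy * (df_b + 2.0) / msx,
        a0=a0,
        b0=b0,
    )


def log_scaled_inv_chi2(s2: float, df: float, S: float) -> float:
    """Log density of the scaled inverse chi-square law.

    Parametrized so that the density is proportional to
    ``(s2)^-(df/2+1) exp(-S/(2 s2))``; mode S/(df+2), mean S/(df-2) for
    df > 2.  Includes the normalising constant (S/2)^(df/2) / Gamma(df/2).
    """
    if s2 <= 0:
        return -np.inf
    half_df = 0.5 * df
    from scipy.special import gammaln

    return float(
        half_df * np.log(0.5 * S)
        - gammaln(half_df)
        - (half_df + 1.0) * np.log(s2)
        - 0.5 * S / s2
    )


def sample_scaled_inv_chi2(df: float, S: float, rng: np.random.Generator) -> float:
    """One draw: S / chi2_df."""
    return float(S / rng.chisquare(df))


def log_rho_prior(rho: float, a0: float, b0: float) -> float:
    """Log density on (-1, 1) induced by rho = 1 - 2B, B ~ Beta(a0, b0).

    Normalised: p(rho) = Beta_pdf((1 - rho)/2; a0, b0) / 2.  Uniform with
    value 1/2 when a0 = b0 = 1.
    """
    if not abs(rho) < 1:
        return -np.inf
    return float(beta_dist.logpdf(0.5 * (1.0 - rho), a0, b0) - np.log(2.0))


def log_prior(state: ModelState, hp: Hyperparameters) -> float:
    """Joint log prior of (beta0, beta, sigma2_e, sigma2_b, rho)."""
    if state.sigma2_e <= 0 or state.sigma2_b <= 0 or not abs(state.rho) < 1:
        return -np.inf
    p = state.beta.size
    lp = -0.5 * state.beta0**2 / hp.sigma2_b0 - 0.5 * np.log(2.0 * np.pi * hp.sigma2_b0)
    lp += (
        -0.5 * np.dot(state.beta, state.beta) / state.sigma2_b
        - 0.5 * p * np.log(2.0 * np.pi * state.sigma2_b)
    )
    lp += log_scaled_inv_chi2(state.sigma2_e, hp.df_e, hp.S_e)
    lp += log_scaled_inv_chi2(state.sigma2_b, hp.df_b, hp.S_b)
    lp += log_rho_prior(state.rho, hp.a0, hp.b0)
    return float(lp)
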