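"""Model comparison (deviance, pD, DIC) and fit/prediction metrics.

The deviance is D(theta) = -2 log p(y | theta) with the *marginal*
(observed-data) likelihood: centered skew-normal for the BSN model and its
rho = 0 Gaussian special case for BRR.  The latent-z (conditional) deviance
is deliberately not used because it is not comparable across the two
models.  The effective number of parameters is pD = Dbar - D(theta_bar)
with theta_bar the posterior means of (beta0, beta, sigma2_e, rho), and
DIC = Dbar + pD; smaller is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augmented import ModelState, RegressionData, marginalized_loglik

__all__ = ["DicResult", "FitMetrics", "deviance", "dic", "fit_metrics"]


@dataclass(frozen=True)
class DicResult:
    mean_deviance: float
    deviance_at_mean: float
    p_d: float
    dic: float


@dataclass(frozen=True)
class FitMetrics:
    """Correlation/error summaries of a fitted model against the truth."""

    cor_y_yhat: float
    mse: float
    cor_signal: float = np.nan   # Cor(X beta_true, X beta_hat)
    cor_beta: float = np.nan     # Cor(beta_true, beta_hat)


def deviance(
    data: RegressionData,
    beta0: float,
    beta: np.ndarray,
    sigma2_e: float,
    rho: float = 0.0,
) -> float:
    """D = -2 * marginal log-likelihood at the given parameter values.

    ``rho = 0`` gives the Gaussian (BRR) deviance exactly.
    """
    state = ModelState(
        beta0=float(beta0), beta=np.asarray(beta, dtype=float),
        sigma2_e=float(sigma2_e), sigma2_b=1.0, rho=float(rho),
    )
    return -2.0 * marginalized_loglik(data, state)


def dic(results, data: RegressionData | None = None) -> DicResult:
    """pD and DIC from fitted-chain draws.

    ``results`` is an :class:`~bsnreg.model.MCMCResults`; the per-draw
    deviances come from the stored marginal log-likelihood chain and the
    plug-in deviance from the posterior means of (beta0, beta, sigma2_e,
    rho).
    """
    chains = results.chains
    if len(chains) == 0:
        raise ValueError("empty chains")
    if data is None:
        data = results.model.data
    mean_dev = float(np.mean(-2.0 * chains.loglik))
    rho_bar = float(chains.rho.mean()) if results.model.has_skew else 0.0
    dev_at_mean = deviance(
        data,
        beta0=float(chains.beta0.mean()),
        beta=chains.beta_mean,
        sigma2_e=float(chains.sigma2_e.mean()),
        rho=rho_bar,
    )
    p_d = mean_dev - dev_at_mean
    return DicResult(
        mean_deviance=mean_dev, deviance_at_mean=dev_at_mean,
        p_d=p_d, dic=mean_dev + p_d,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("length mismatch in correlation")
    if a.std() == 0 or b.std() == 0:
        return np.nan  # undefined, deliberately not coerced to 0
    return float(np.corrcoef(a, b)[0, 1])


def fit_metrics(y, yhat, beta_true=None, beta_hat=None, X=None) -> FitMetrics:
    """Pearson correlations and MSE used in the simulation summaries.

    Always reports Cor(y, yhat) and MSE; when the true effects are known
    (simulation), also Cor(beta, beta_hat) and the genetic-signal
    correlation Cor(X beta, X beta_hat).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size != yhat.size:
        raise ValueError("y and yhat lengths differ")
    cor = _pearson(y, yhat)
    mse = float(np.mean((y - yhat) ** 2))
    cor_signal = cor_beta = np.nan
    if beta_true is not None and beta_hat is not None:
        cor_beta = _pearson(beta_true, beta_hat)
        if X is not None:
            X = np.asarray(X, dtype=float)
            cor_signal = _pearson(X @ np.asarray(beta_true, float),
                                  X @ np.asarray(beta_hat, float))
    return FitMetrics(cor_y_yhat=cor, mse=mse, cor_signal=cor_signal, cor_beta=cor_beta)
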