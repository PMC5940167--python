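"""Model classes for Bayesian whole-genome regression.

Two models share the ridge-type prior on marker effects:

* :class:`SkewNormalRegression` (BSN) — residuals follow the centered
  skew-normal law SN_C(0, sigma2_e, gamma1(rho)); fitted by Gibbs sampling
  with hidden-truncation data augmentation plus random-walk Metropolis for
  (rho, sigma2_e).
* :class:`BayesianRidge` (BRR) — Gaussian residuals, the rho = 0 special
  case; fitted by an all-Gibbs sampler.

Both follow the Model/Results pattern: build the model from (y, X), call
``fit`` to run the sampler, and work with the returned :class:`MCMCResults`
(posterior chains, summaries, prediction, DIC).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _fast
from .augmented import ModelState, RegressionData
from .hyperparams import Hyperparameters, default_hyperparameters
from .kernels import reference_bsn_scan, reference_brr_scan

__all__ = [
    "MCMCConfig",
    "PosteriorChains",
    "MCMCResults",
    "SkewNormalRegression",
    "BayesianRidge",
    "fit_bsn",
    "fit_brr",
    "predict",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    Defaults mirror the long-run analysis protocol (100,000 retained draws
    after a 50,000-iteration burn-in); use far shorter chains for testing.
    """

    n_iter: int = 150_000
    burn_in: int = 50_000
    thin: int = 1
    seed: int = 0
    rho_step: float = 0.1
    sig_step: float = 0.1
    adapt_target: float = 0.23
    adapt_window: int = 100
    store_beta: bool = False
    engine: str = "fast"  # "fast" (numba) or "reference" (numpy kernels)

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.rho_step <= 0 or self.sig_step <= 0:
            raise ValueError("proposal steps must be positive")
        if not 0 < self.adapt_target < 1:
            raise ValueError("adapt_target must lie in (0, 1)")
        if self.engine not in ("fast", "reference"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass
class PosteriorChains:
    """Retained post-burn-in draws and sampler diagnostics."""

    beta0: np.ndarray
    sigma2_e: np.ndarray
    sigma2_b: np.ndarray
    rho: np.ndarray
    loglik: np.ndarray          # marginal (observed-data) log-likelihood
    beta_mean: np.ndarray       # posterior mean of marker effects
    beta_draws: np.ndarray | None = None
    accept_rate_rho: float = np.nan
    accept_rate_sigma: float = np.nan
    rho_step_final: float = np.nan
    sig_step_final: float = np.nan

    def __len__(self) -> int:
        return self.beta0.size

    def to_frame(self) -> pd.DataFrame:
        """Scalar chains as a tidy table, one row per retained iteration."""
        return pd.DataFrame(
            {
                "iter": np.arange(len(self)),
                "beta0": self.beta0,
                "sigma2_e": self.sigma2_e,
                "sigma2_b": self.sigma2_b,
                "rho": self.rho,
                "loglik": self.loglik,
            }
        )


class MCMCResults:
    """Posterior summaries for a fitted whole-genome regression.

    Attributes
    ----------
    chains : PosteriorChains
        Retained draws of all scalar parameters and the running posterior
        mean of the marker effects.
    params : pandas.Series
        Posterior means of beta0, sigma2_e, sigma2_b (and rho for the
        skew-normal model).
    """

    def __init__(self, model, chains: PosteriorChains, config: MCMCConfig):
        self.model = model
        self.chains = chains
        self.config = config
        names = ["beta0", "sigma2_e", "sigma2_b"]
        vals = [chains.beta0.mean(), chains.sigma2_e.mean(), chains.sigma2_b.mean()]
        sds = [
            chains.beta0.std(ddof=1),
            chains.sigma2_e.std(ddof=1),
            chains.sigma2_b.std(ddof=1),
        ]
        if model.has_skew:
            names.append("rho")
            vals.append(chains.rho.mean())
            sds.append(chains.rho.std(ddof=1))
        self.params = pd.Series(vals, index=names)
        self.posterior_sd = pd.Series(sds, index=names)

    @property
    def beta0(self) -> float:
        return float(self.params["beta0"])

    @property
    def beta(self) -> np.ndarray:
        """Posterior mean of the marker effects."""
        return self.chains.beta_mean

    @property
    def theta(self) -> float:
        """Regularization ratio sigma2_e-hat / sigma2_b-hat."""
        return float(self.params["sigma2_e"] / self.params["sigma2_b"])

    def predict(self, X_new: np.ndarray | None = None) -> np.ndarray:
        """Posterior-mean prediction beta0_hat + X_new @ beta_hat.

        With the centered residual parametrization E(e) = 0, so no skewness
        correction enters the predictive mean.
        """
        if X_new is None:
            X_new = self.model.data.X
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim != 2 or X_new.shape[1] != self.beta.size:
            raise ValueError(
                f"X_new must have {self.beta.size} columns, got shape {X_new.shape}"
            )
        return self.beta0 + X_new @ self.beta

    def dic(self):
        """Deviance information criterion of the fit (marginal likelihood)."""
        from .evaluate import dic as _dic

        return _dic(self, self.model.data)

    def summary(self) -> str:
        dic_res = self.dic()
        head = (
            f"{type(self.model).__name__} fit: n={self.model.data.n}, "
            f"p={self.model.data.p}, retained draws={len(self.chains)}\n"
        )
        tab = pd.DataFrame(
            {"post.mean": self.params, "post.sd": self.posterior_sd}
        ).to_string(float_format=lambda v: f"{v:.5g}")
        extra = (
            f"\ntheta = sigma2_e/sigma2_b = {self.theta:.4g}"
            f"\npD = {dic_res.p_d:.3f}   DIC = {dic_res.dic:.3f}"
        )
        if self.model.has_skew:
            extra += (
                f"\nMetropolis acceptance (rho, sigma2_e) = "
                f"({self.chains.accept_rate_rho:.3f}, {self.chains.accept_rate_sigma:.3f})"
            )
        return head + tab + extra


class _BaseGenomicRegression:
    has_skew = False

    def __init__(self, endog, exog, hyper: Hyperparameters | None = None):
        self.data = RegressionData(np.asarray(endog, dtype=float), np.asarray(exog, dtype=float))
        self.hyper = hyper if hyper is not None else default_hyperparameters(self.data)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, phenotype: str, markers=None, **kw):
        """Build from a DataFrame with a phenotype column and marker columns."""
        if markers is None:
            markers = [c for c in frame.columns if c != phenotype]
        return cls(frame[phenotype].to_numpy(), frame[markers].to_numpy(), **kw)

    def _init_state(self) -> tuple[float, float, float]:
        vy = float(np.var(self.data.y, ddof=1))
        return (
            float(self.data.y.mean()),
            vy / 2.0,
            self.hyper.S_b / (self.hyper.df_b + 2.0),
        )


class SkewNormalRegression(_BaseGenomicRegression):
    """Bayesian whole-genome regression with skew-normal residuals (BSN)."""

    has_skew = True

    def fit(self, config: MCMCConfig | None = None, *, fix_rho: float | None = None,
            **config_kw) -> MCMCResults:
        """Run the data-augmentation MCMC sampler.

        Parameters
        ----------
        config : MCMCConfig, optional
            Sampler settings; keyword overrides may be passed directly
            (e.g. ``fit(n_iter=10_000, burn_in=5_000, seed=1)``).
        fix_rho : float, optional
            Freeze the shape parameter at this value (disables the rho
            Metropolis step).  ``fix_rho=0.0`` gives the Gaussian submodel.
        """
        config = _resolve_config(config, config_kw)
        beta0_0, s2e_0, s2b_0 = self._init_state()
        hp = self.hyper
        if config.engine == "fast":
            Xt = np.ascontiguousarray(self.data.X.T)
            ss = np.einsum("ji,ji->j", Xt, Xt)
            out = _fast.run_bsn_chain(
                self.data.y, Xt, ss,
                hp.sigma2_b0, hp.df_e, hp.S_e, hp.df_b, hp.S_b, hp.a0, hp.b0,
                config.n_iter, config.burn_in, config.thin,
                config.seed,
                config.rho_step, config.sig_step, config.adapt_target,
                config.adapt_window,
                fix_rho is not None, 0.0 if fix_rho is None else float(fix_rho),
                beta0_0, s2e_0, s2b_0,
                config.store_beta,
            )
            (b0c, s2ec, s2bc, rhoc, llc, bmean, bdraws,
             acc_rho, acc_sig, rho_step_f, sig_step_f) = out
            chains = PosteriorChains(
                beta0=b0c, sigma2_e=s2ec, sigma2_b=s2bc, rho=rhoc, loglik=llc,
                beta_mean=bmean,
                beta_draws=bdraws if config.store_beta else None,
                accept_rate_rho=float(acc_rho), accept_rate_sigma=float(acc_sig),
                rho_step_final=float(rho_step_f), sig_step_final=float(sig_step_f),
            )
        else:
            chains = _reference_chain(self, config, fix_rho=fix_rho)
        if not np.all(np.isfinite(chains.beta0)):
            raise RuntimeError("sampler produced non-finite draws; check inputs")
        return MCMCResults(self, chains, config)


class BayesianRidge(_BaseGenomicRegression):
    """Bayesian ridge regression with Gaussian residuals (BRR)."""

    has_skew = False

    def fit(self, config: MCMCConfig | None = None, **config_kw) -> MCMCResults:
        config = _resolve_config(config, config_kw)
        beta0_0, s2e_0, s2b_0 = self._init_state()
        hp = self.hyper
        if config.engine == "fast":
            Xt = np.ascontiguousarray(self.data.X.T)
            ss = np.einsum("ji,ji->j", Xt, Xt)
            b0c, s2ec, s2bc, llc, bmean, bdraws = _fast.run_brr_chain(
                self.data.y, Xt, ss,
                hp.sigma2_b0, hp.df_e, hp.S_e, hp.df_b, hp.S_b,
                config.n_iter, config.burn_in, config.thin,
                config.seed,
                beta0_0, s2e_0, s2b_0,
                config.store_beta,
            )
            chains = PosteriorChains(
                beta0=b0c, sigma2_e=s2ec, sigma2_b=s2bc,
                rho=np.zeros_like(b0c), loglik=llc, beta_mean=bmean,
                beta_draws=bdraws if config.store_beta else None,
            )
        else:
            chains = _reference_chain(self, config, brr=True)
        return MCMCResults(self, chains, config)


def _resolve_config(config: MCMCConfig | None, overrides: dict) -> MCMCConfig:
    if config is None:
        config = MCMCConfig()
    if overrides:
        config = replace(config, **overrides)
    return config


def _reference_chain(model, config: MCMCConfig, fix_rho=None, brr: bool = False) -> PosteriorChains:
    """Pure-numpy sampler path built from the unit-tested kernels."""
    from .augmented import marginalized_loglik

    data, hp = model.data, model.hyper
    rng = np.random.default_rng(config.seed)
    beta0_0, s2e_0, s2b_0 = model._init_state()
    state = ModelState(
        beta0=beta0_0, beta=np.zeros(data.p), sigma2_e=s2e_0, sigma2_b=s2b_0,
        rho=0.0 if (brr or fix_rho is None) else float(fix_rho),
        z=np.full(data.n, np.sqrt(2.0 / np.pi)),
    )
    if fix_rho is not None:
        state.rho = float(fix_rho)
    n_keep = (config.n_iter - config.burn_in) // config.thin
    b0c = np.empty(n_keep)
    s2ec = np.empty(n_keep)
    s2bc = np.empty(n_keep)
    rhoc = np.empty(n_keep)
    llc = np.empty(n_keep)
    bmean = np.zeros(data.p)
    bdraws = np.zeros((n_keep, data.p)) if config.store_beta else None

    rho_step, sig_step = config.rho_step, config.sig_step
    acc_rho_w = acc_sig_w = 0
    n_batches = 0
    acc_rho_post = acc_sig_post = n_post = 0
    half_batches = max(1, (config.burn_in // config.adapt_window) // 2)
    log_rho_sum = log_sig_sum = 0.0
    n_avg = 0
    keep = 0
    for it in range(config.n_iter):
        if brr:
            reference_brr_scan(data, state, hp, rng)
        else:
            acc_r, acc_s = reference_bsn_scan(
                data, state, hp, rng, rho_step=rho_step, sig_step=sig_step,
                fix_rho=fix_rho is not None,
            )
            if it < config.burn_in:
                acc_rho_w += acc_r
                acc_sig_w += acc_s
                if (it + 1) % config.adapt_window == 0:
                    n_batches += 1
                    gain = min(1.0, max(0.5, 3.0 / np.sqrt(n_batches)))
                    rate_r = acc_rho_w / config.adapt_window
                    rate_s = acc_sig_w / config.adapt_window
                    if fix_rho is None:
                        rho_step *= np.exp(gain * (rate_r - config.adapt_target))
                    sig_step *= np.exp(gain * (rate_s - config.adapt_target))
                    acc_rho_w = acc_sig_w = 0
                    if n_batches > half_batches:
                        log_rho_sum += np.log(rho_step)
                        log_sig_sum += np.log(sig_step)
                        n_avg += 1
                    if it + 1 + config.adapt_window > config.burn_in and n_avg > 0:
                        rho_step = float(np.exp(log_rho_sum / n_avg))
                        sig_step = float(np.exp(log_sig_sum / n_avg))
            else:
                acc_rho_post += acc_r
                acc_sig_post += acc_s
                n_post += 1
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and keep < n_keep:
            b0c[keep] = state.beta0
            s2ec[keep] = state.sigma2_e
            s2bc[keep] = state.sigma2_b
            rhoc[keep] = state.rho
            llc[keep] = marginalized_loglik(data, state)
            bmean += state.beta
            if bdraws is not None:
                bdraws[keep] = state.beta
            keep += 1
    bmean /= n_keep
    return PosteriorChains(
        beta0=b0c, sigma2_e=s2ec, sigma2_b=s2bc, rho=rhoc, loglik=llc,
        beta_mean=bmean, beta_draws=bdraws,
        accept_rate_rho=(acc_rho_post / n_post) if (n_post and not brr and fix_rho is None) else np.nan,
        accept_rate_sigma=(acc_sig_post / n_post) if (n_post and not brr) else np.nan,
        rho_step_final=rho_step, sig_step_final=sig_step,
    )


def fit_bsn(data: RegressionData, hyper: Hyperparameters | None = None,
            config: MCMCConfig | None = None, **kw) -> MCMCResults:
    """Fit the skew-normal regression; thin functional wrapper."""
    return SkewNormalRegression(data.y, data.X, hyper=hyper).fit(config, **kw)


def fit_brr(data: RegressionData, hyper: Hyperparameters | None = None,
            config: MCMCConfig | None = None, **kw) -> MCMCResults:
    """Fit the Bayesian ridge regression; thin functional wrapper."""
    return BayesianRidge(data.y, data.X, hyper=hyper).fit(config, **kw)


def predict(results: MCMCResults, X_new: np.ndarray) -> np.ndarray:
    """Posterior-mean phenotype prediction for new marker genotypes."""
    return results.predict(X_new)
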