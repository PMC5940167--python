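"""Synthetic-data generation and the simulation / cross-validation harnesses.

The Monte-Carlo harness emulates the standard genomic-prediction simulation
design: an additive genetic model

    y_i = beta0 + sum_j x_ij beta_j + e_i,

with a sparse effect vector (10 nonzero effects drawn N(0, 0.5/10)) over a
binary DArT-style marker panel, intercept beta0 = 3, and centered
skew-normal residuals e_i ~ SN_C(0, 1.5^2, gamma1(rho)) whose shape rho is
varied over {0, .5, .75, .90, .95, .99} to produce increasing skewness.
Marker genotypes are iid Bernoulli(maf) (or Binomial(2, maf) for 0/1/2 SNP
coding); linkage structure is immaterial to the residual-model contrast the
harness probes, so no LD is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .augmented import RegressionData
from .evaluate import dic, fit_metrics
from .model import BayesianRidge, MCMCConfig, SkewNormalRegression
from .skewnormal import rsn_hidden_truncation, sn_constants

__all__ = [
    "WHEAT_EFFECT_INDICES",
    "SimulationSettings",
    "synth_markers",
    "default_effect_indices",
    "simulate_phenotypes",
    "run_monte_carlo",
    "cross_validate",
]

#: 1-based positions of the ten causal markers on the classic 1279-marker
#: wheat DArT panel used by the simulation design.
WHEAT_EFFECT_INDICES = (63, 190, 317, 444, 571, 698, 825, 952, 1079, 1206)


def default_effect_indices(p: int, n_effects: int = 10) -> tuple[int, ...]:
    """Evenly spaced 1-based causal positions: round(p*k/(n_effects+1))."""
    if p == 1279 and n_effects == 10:
        return WHEAT_EFFECT_INDICES
    if n_effects > p:
        raise ValueError(f"cannot place {n_effects} distinct effects among {p} markers")
    idx = tuple(int(round(p * k / (n_effects + 1))) for k in range(1, n_effects + 1))
    if len(set(idx)) != n_effects or min(idx) < 1:
        # dense case: spread over the full 1..p range instead
        idx = tuple(int(v) for v in np.round(np.linspace(1, p, n_effects)))
    return idx


@dataclass(frozen=True)
class SimulationSettings:
    """Generative configuration of the Monte-Carlo study."""

    n: int = 599
    p: int = 1279
    marker_coding: str = "0/1"      # "0/1" (DArT) or "0/1/2" (SNP)
    maf: float = 0.5
    beta0_true: float = 3.0
    effect_indices: tuple[int, ...] | None = None  # 1-based; None -> default grid
    effect_variance: float = 0.5 / 10.0
    sigma_e_true: float = 1.5
    rho_true: float = 0.0
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.maf < 1:
            raise ValueError("maf must lie strictly between 0 and 1")
        if self.marker_coding not in ("0/1", "0/1/2"):
            raise ValueError("marker_coding must be '0/1' or '0/1/2'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not abs(self.rho_true) < 1:
            raise ValueError("rho_true must lie in (-1, 1)")
        idx = self.effect_indices
        if idx is None:
            idx = default_effect_indices(self.p, n_effects=min(10, self.p))
            object.__setattr__(self, "effect_indices", idx)
        if min(idx) < 1 or max(idx) > self.p:
            raise ValueError("effect indices must lie in 1..p")


def synth_markers(n: int, p: int, maf: float = 0.5, coding: str = "0/1",
                  seed=None) -> np.ndarray:
    """Simulate an n x p marker matrix with iid genotype codes.

    Bernoulli(maf) entries for "0/1" coding, Binomial(2, maf) for "0/1/2".
    Constant columns (monomorphic in the sample) are resampled so every
    marker is usable as a covariate.
    """
    if not 0 < maf < 1:
        raise ValueError("maf must lie strictly between 0 and 1")
    if coding not in ("0/1", "0/1/2"):
        raise ValueError("coding must be '0/1' or '0/1/2'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_trials = 1 if coding == "0/1" else 2
    X = rng.binomial(n_trials, maf, size=(n, p)).astype(float)
    for _ in range(1000):
        const = np.flatnonzero(X.min(axis=0) == X.max(axis=0))
        if const.size == 0:
            break
        X[:, const] = rng.binomial(n_trials, maf, size=(n, const.size))
    else:
        raise RuntimeError("could not avoid monomorphic marker columns")
    return X


def simulate_phenotypes(X: np.ndarray, settings: SimulationSettings,
                        replicate_seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (y, beta_true) for one replicate of the additive model.

    The nonzero effects sit at ``settings.effect_indices`` (1-based) and are
    drawn N(0, effect_variance); the residuals are exact centered
    skew-normal draws sigma_e * (U - EU)/SU with U from the
    hidden-truncation sampler, so they have mean 0, variance sigma_e^2 and
    skewness gamma1(rho_true).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if max(settings.effect_indices) > p:
        raise ValueError("effect indices out of range for this marker matrix")
    rng = (replicate_seed if isinstance(replicate_seed, np.random.Generator)
           else np.random.default_rng(replicate_seed))
    beta = np.zeros(p)
    idx = np.asarray(settings.effect_indices, dtype=int) - 1
    beta[idx] = rng.normal(0.0, np.sqrt(settings.effect_variance), size=idx.size)
    k = sn_constants(settings.rho_true)
    u = rsn_hidden_truncation(n, settings.rho_true, seed=rng)
    e = settings.sigma_e_true * (u - k.EU) / k.SU
    y = settings.beta0_true + X @ beta + e
    return y, beta


def _replicate_row(model_name, res, data, y, beta_true):
    m = fit_metrics(y, res.predict(), beta_true, res.beta, data.X)
    d = dic(res)
    row = {
        "model": model_name,
        "beta0_hat": res.params["beta0"],
        "sigma2_e_hat": res.params["sigma2_e"],
        "sigma2_b_hat": res.params["sigma2_b"],
        "theta_hat": res.theta,
        "rho_hat": res.params.get("rho", np.nan),
        "cor_y_yhat": m.cor_y_yhat,
        "mse": m.mse,
        "cor_beta": m.cor_beta,
        "cor_signal": m.cor_signal,
        "pD": d.p_d,
        "DIC": d.dic,
    }
    return row


def run_monte_carlo(settings: SimulationSettings,
                    mcmc_config: MCMCConfig | None = None,
                    models: tuple[str, ...] = ("BSN", "BRR")) -> pd.DataFrame:
    """Replicated simulate-fit-evaluate loop over BSN and BRR.

    Returns one row per (replicate, model) with posterior summaries, fit
    metrics, pD and DIC.  Fully deterministic given ``settings.seed`` and
    ``mcmc_config.seed``.  Replicate failures are recorded in an ``error``
    column rather than silently dropped.
    """
    if mcmc_config is None:
        mcmc_config = MCMCConfig()
    master = np.random.default_rng(settings.seed)
    X = synth_markers(settings.n, settings.p, settings.maf,
                      settings.marker_coding, seed=master)
    rows = []
    for rep in range(settings.n_replicates):
        rep_seed = int(master.integers(2**31 - 1))
        chain_seed = int(mcmc_config.seed + 7919 * rep + 1)
        y, beta_true = simulate_phenotypes(X, settings, replicate_seed=rep_seed)
        data = RegressionData(y, X)
        try:
            fits = []
            if "BSN" in models:
                fits.append(("BSN", SkewNormalRegression(y, X).fit(
                    replace(mcmc_config, seed=chain_seed))))
            if "BRR" in models:
                fits.append(("BRR", BayesianRidge(y, X).fit(
                    replace(mcmc_config, seed=chain_seed + 1))))
            for name, res in fits:
                row = _replicate_row(name, res, data, y, beta_true)
                row.update(replicate=rep, rho_true=settings.rho_true, error="")
                rows.append(row)
        except Exception as exc:  # record, don't drop
            rows.append({"replicate": rep, "model": "BSN",
                         "rho_true": settings.rho_true, "error": repr(exc)})
    return pd.DataFrame(rows)


def cross_validate(data: RegressionData, n_partitions: int = 100,
                   test_fraction: float = 0.2,
                   mcmc_config: MCMCConfig | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Random-partition cross-validation of BSN vs BRR predictive ability.

    For each partition, both models are trained on (1 - test_fraction) of
    the lines and evaluated on the held-out fraction with Pearson
    correlation and MSE; ``bsn_wins_cor`` / ``bsn_wins_mse`` flag the
    partitions where the skew-normal model predicts better.
    """
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    n_test = int(round(data.n * test_fraction))
    if n_test < 3:
        raise ValueError("test set smaller than 3 observations")
    if mcmc_config is None:
        mcmc_config = MCMCConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for part in range(n_partitions):
        perm = rng.permutation(data.n)
        test, train = perm[:n_test], perm[n_test:]
        y_tr, X_tr = data.y[train], data.X[train]
        y_te, X_te = data.y[test], data.X[test]
        chain_seed = int(mcmc_config.seed + 7919 * part + 1)
        bsn = SkewNormalRegression(y_tr, X_tr).fit(replace(mcmc_config, seed=chain_seed))
        brr = BayesianRidge(y_tr, X_tr).fit(replace(mcmc_config, seed=chain_seed + 1))
        m_bsn = fit_metrics(y_te, bsn.predict(X_te))
        m_brr = fit_metrics(y_te, brr.predict(X_te))
        rows.append({
            "partition": part,
            "cor_bsn": m_bsn.cor_y_yhat, "cor_brr": m_brr.cor_y_yhat,
            "mse_bsn": m_bsn.mse, "mse_brr": m_brr.mse,
            "bsn_wins_cor": m_bsn.cor_y_yhat > m_brr.cor_y_yhat,
            "bsn_wins_mse": m_bsn.mse < m_brr.mse,
        })
    return pd.DataFrame(rows)
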