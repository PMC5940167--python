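import numpy as np
import pytest

from bsnreg import RegressionData, SimulationSettings, simulate_phenotypes, synth_markers


@pytest.fixture(scope="session")
def small_skewed_dataset():
    """A small simulated dataset with strongly skewed residuals (rho=0.9)."""
    X = synth_markers(120, 40, seed=101)
    settings = SimulationSettings(n=120, p=40, rho_true=0.9, n_replicates=1, seed=101)
    y, beta_true = simulate_phenotypes(X, settings, replicate_seed=202)
    return RegressionData(y, X), beta_true, settings


@pytest.fixture(scope="session")
def small_normal_dataset():
    """A small simulated dataset with Gaussian residuals (rho=0)."""
    X = synth_markers(150, 20, seed=303)
    settings = SimulationSettings(n=150, p=20, rho_true=0.0, n_replicates=1, seed=303)
    y, beta_true = simulate_phenotypes(X, settings, replicate_seed=404)
    return RegressionData(y, X), beta_true, settings


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
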