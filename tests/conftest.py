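import numpy as np
import pytest

from epiflex import SimConfig, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240228)


@pytest.fixture
def hwe_pair(rng):
    """A pair of independent HWE loci (m=200) plus a noisy phenotype with a
    genuine product interaction."""
    m = 200
    g1 = rng.binomial(2, 0.3, m).astype(float)
    g2 = rng.binomial(2, 0.4, m).astype(float)
    p = 0.2 * g1 - 0.1 * g2 + 0.4 * g1 * g2 + rng.normal(size=m)
    return g1, g2, p


@pytest.fixture
def small_genotypes():
    return simulate_genotypes(SimConfig(m=300, n_loci=6, seed=5))


def ols_interaction(g1, g2, I, p):
    """Independent oracle: interaction coefficient and t-value from a full
    OLS fit with intercept on the raw (uncentered) variables."""
    m = len(p)
    X = np.column_stack([np.ones(m), g1, g2, I])
    beta, *_ = np.linalg.lstsq(X, p, rcond=None)
    resid = p - X @ beta
    sigma2 = resid @ resid / (m - X.shape[1])
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta[3], beta[3] / np.sqrt(cov[3, 3])
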