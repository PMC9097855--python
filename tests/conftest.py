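import numpy as np
import pytest

import connmed
from connmed import genetics as gen


@pytest.fixture(scope="session")
def small_bundle():
    """Moderate full-mediation cohort shared across read-only tests."""
    return connmed.scenario("full_mediation", 400, seed=11, n_snps=60, K=6)


@pytest.fixture(scope="session")
def small_covariates(small_bundle):
    return gen.make_covariate_table(small_bundle.covariates, small_bundle.genotypes)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent oracle: solve (X'X) b = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def bh_brute_force(p: np.ndarray, q: float):
    """Direct BH definition: largest i with p_(i) <= i q / m; adjusted p by
    the min-over-tail formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = q * (np.arange(1, m + 1)) / m
    below = np.nonzero(sorted_p <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, sorted_p[i] * m / (i + 1))
        adj[order[i]] = running
    return reject, adj
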