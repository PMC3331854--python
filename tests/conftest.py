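import numpy as np
import pytest

import penreml as pr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pair(rng, q, lam_lo=0.05, lam_hi=0.95):
    """Random covariance pair with canonical eigenvalues interior to (0,1)."""
    lam = np.sort(rng.uniform(lam_lo, lam_hi, q))[::-1]
    A = rng.standard_normal((q, q))
    sigma_P = A @ A.T + q * np.eye(q)
    T = np.linalg.cholesky(sigma_P)
    return pr.canonical_compose(pr.CanonicalForm(lambdas=lam, T=T))


@pytest.fixture
def pair_factory():
    return random_pair


@pytest.fixture
def toy_q1_stats():
    """Single-trait stats with an interior ANOVA solution."""
    return pr.HalfSibStats(s=100, n=10, M_B=[[2.0]], M_W=[[0.9]])


@pytest.fixture
def small_scenario():
    """Two-trait scenario used for quick simulation-based checks."""
    return pr.build_scenario("toy2", [0.4, 0.3], "I", phen_var=[1.0, 2.0])
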