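import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def default_cfg():
    from lhsdrive.config import default_config
    return default_config(seed=777)


def random_stable_coupling(rng, max_rho=0.9):
    """Random nonnegative zero-diagonal 4x4 matrix with rho <= max_rho."""
    K = rng.uniform(0, 1, size=(4, 4))
    np.fill_diagonal(K, 0.0)
    rho = np.max(np.abs(np.linalg.eigvals(K)))
    if rho > 0:
        K *= rng.uniform(0.1, 1.0) * max_rho / rho
    return K


def kappa_oracle(x, y, scheme="quadratic", n_cat=5):
    """Direct O(k^2) weighted-kappa computation from the contingency
    table; independent of the implementation under test."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    obs = np.zeros((n_cat, n_cat))
    for a, b in zip(x, y):
        obs[a, b] += 1
    obs /= obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    i, j = np.meshgrid(np.arange(n_cat), np.arange(n_cat), indexing="ij")
    if scheme == "linear":
        w = np.abs(i - j) / (n_cat - 1)
    else:
        w = ((i - j) / (n_cat - 1)) ** 2
    denom = np.sum(w * expected)
    if denom == 0:
        return None
    return 1.0 - np.sum(w * obs) / denom


def neumann_oracle(K, f, terms=50):
    """Truncated Neumann series sum_{n=0}^{terms} K^n f."""
    K = np.asarray(K, dtype=float)
    f = np.asarray(f, dtype=float)
    acc = f.copy()
    term = f.copy()
    for _ in range(terms):
        term = K @ term
        acc = acc + term
    return acc
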