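import numpy as np
import pytest

from spillnet.synthetic_data import (
    SimulationConfig,
    generate_expenditure_panel,
    make_calendar,
    random_innovation_cov,
    random_stationary_coefficients,
)
from spillnet.tvp_var import VARParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bivariate_params():
    """Fixed bivariate VAR(1) used by the decomposition oracle tests."""
    a = np.array([[[0.5, 0.2], [0.1, 0.4]]])
    sigma = np.array([[1.0, 0.3], [0.3, 0.8]])
    return VARParams(np.zeros(2), a, sigma)


@pytest.fixture
def small_panel():
    """Seeded 3-series weekly panel from a known stationary VAR(1)."""
    rng = np.random.default_rng(42)
    coefs = random_stationary_coefficients(3, 1, rng, target_radius=0.5)
    cov = random_innovation_cov(3, rng)
    cal = make_calendar("2000-01-01", "2007-12-31")
    config = SimulationConfig(
        calendar=cal, coefficients=coefs, innovation_cov=cov, n_series=3, seed=7
    )
    panel = generate_expenditure_panel(config)
    return panel, coefs, cov


def impulse_response_psis(coefs: np.ndarray, horizon: int) -> list[np.ndarray]:
    """Oracle MA matrices by direct recursion of the difference equation:
    column j of Psi_h is the response at step h to a unit impulse e_j."""
    p, n, _ = coefs.shape
    psis = []
    for h in range(horizon + 1):
        mat = np.zeros((n, n))
        psis.append(mat)
    for j in range(n):
        hist = [np.zeros(n) for _ in range(p)]  # y_{t-1}, ..., y_{t-p}
        shock = np.zeros(n)
        shock[j] = 1.0
        for h in range(horizon + 1):
            y = shock.copy() if h == 0 else np.zeros(n)
            for lag in range(p):
                y = y + coefs[lag] @ hist[lag]
            psis[h][:, j] = y
            hist = [y] + hist[:-1]
    return psis


def oracle_gfevd(coefs: np.ndarray, sigma: np.ndarray, horizon: int) -> np.ndarray:
    """Brute-force generalized FEVD by explicit MA accumulation (scalar loops)."""
    n = sigma.shape[0]
    psis = impulse_response_psis(coefs, horizon - 1)
    theta = np.zeros((n, n))
    for i in range(n):
        den = 0.0
        for h in range(horizon):
            row = psis[h][i, :]
            den += float(row @ sigma @ row)
        for j in range(n):
            num = 0.0
            for h in range(horizon):
                num += float(psis[h][i, :] @ sigma[:, j]) ** 2
            theta[i, j] = num / (sigma[j, j] * den)
    return theta / theta.sum(axis=1, keepdims=True)
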