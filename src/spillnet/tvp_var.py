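"""Vector-autoregression estimation: constant-parameter OLS and a
time-varying-parameter Kalman filter with forgetting factors.

The TVP filter treats the stacked coefficient vector as a random-walk state.
Two scalars in (0, 1] control adaptivity: ``kappa1`` inflates the coefficient
uncertainty each step (coefficient forgetting) and ``kappa2`` drives an
exponentially weighted update of the innovation covariance.  With both set to
one the filter collapses to recursive least squares and, under a diffuse
prior, its final state reproduces the full-sample OLS fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VARParams",
    "TVPVARState",
    "companion_matrix",
    "spectral_radius",
    "fit_ols_var",
    "select_var_order",
    "fit_tvp_var",
    "ma_coefficients",
]


def companion_matrix(coefs: np.ndarray) -> np.ndarray:
    """Companion form of a (p, N, N) coefficient stack."""
    coefs = np.asarray(coefs, dtype=float)
    if coefs.ndim != 3 or coefs.shape[1] != coefs.shape[2]:
        raise ValueError(f"coefficient stack must have shape (p, N, N), got {coefs.shape}")
    p, n, _ = coefs.shape
    top = np.hstack([coefs[j] for j in range(p)])
    if p == 1:
        return top
    bottom = np.hstack([np.eye(n * (p - 1)), np.zeros((n * (p - 1), n))])
    return np.vstack([top, bottom])


def spectral_radius(coefs: np.ndarray) -> float:
    """Modulus of the largest companion eigenvalue; < 1 means stationary."""
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coefs)))))


@dataclass
class VARParams:
    """Constant VAR(p) parameters: intercept, lag matrices and innovation covariance."""

    intercept: np.ndarray  # (N,)
    coefs: np.ndarray  # (p, N, N); coefs[j] multiplies y_{t-j-1}
    sigma: np.ndarray  # (N, N)

    def __post_init__(self) -> None:
        self.intercept = np.asarray(self.intercept, dtype=float)
        self.coefs = np.asarray(self.coefs, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.intercept.shape[0]
        if self.coefs.ndim != 3 or self.coefs.shape[1:] != (n, n):
            raise ValueError("coefs must have shape (p, N, N) matching the intercept")
        if self.sigma.shape != (n, n):
            raise ValueError("sigma must be N x N")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")

    @property
    def order(self) -> int:
        return self.coefs.shape[0]

    @property
    def n_series(self) -> int:
        return self.intercept.shape[0]

    @property
    def companion_spectral_radius(self) -> float:
        return spectral_radius(self.coefs)

    def is_stationary(self, tol: float = 0.0) -> bool:
        return self.companion_spectral_radius < 1.0 - tol


@dataclass
class TVPVARState:
    """One period of the forgetting-factor filter.

    ``uncertainty`` holds the posterior covariance of the stacked coefficient
    vector; to bound memory the filter stores only its diagonal by default
    (``store_uncertainty='diag'``).
    """

    t: int
    intercept: np.ndarray
    coefs: np.ndarray
    sigma: np.ndarray
    uncertainty: np.ndarray
    kappa1: float
    kappa2: float

    def params(self) -> VARParams:
        return VARParams(self.intercept, self.coefs, self.sigma)


def _lag_design(values: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (Y, X) for y_t = B [1, y_{t-1}, ..., y_{t-p}]' + e_t."""
    t_total, n = values.shape
    rows = t_total - p
    x = np.empty((rows, n * p + 1))
    x[:, 0] = 1.0
    for j in range(p):
        x[:, 1 + j * n : 1 + (j + 1) * n] = values[p - 1 - j : t_total - 1 - j]
    return values[p:], x


def fit_ols_var(values: np.ndarray, p: int) -> VARParams:
    """Equation-by-equation least-squares VAR(p) with intercept.

    The innovation covariance uses the residual cross-product matrix with a
    degrees-of-freedom correction T_eff - (N*p + 1).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a (T, N) array")
    if not np.all(np.isfinite(values)):
        raise ValueError("values contain non-finite entries")
    t_total, n = values.shape
    if p < 1:
        raise ValueError("p must be >= 1")
    k = n * p + 1
    if t_total - p <= k:
        raise ValueError(f"need more than N*p+1={k} usable observations, have {t_total - p}")
    y, x = _lag_design(values, p)
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        raise np.linalg.LinAlgError(f"regressor matrix is rank deficient (rank {rank} < {k})")
    b, *_ = np.linalg.lstsq(x, y, rcond=None)  # (k, N)
    resid = y - x @ b
    dof = y.shape[0] - k
    sigma = resid.T @ resid / dof
    intercept = b[0]
    coefs = np.stack([b[1 + j * n : 1 + (j + 1) * n].T for j in range(p)])
    return VARParams(intercept, coefs, 0.5 * (sigma + sigma.T))


def select_var_order(values: np.ndarray, max_p: int = 4) -> int:
    """Pick the VAR lag order by BIC over 1..max_p on a common sample."""
    values = np.asarray(values, dtype=float)
    t_total, n = values.shape
    best_p, best_bic = 1, np.inf
    for p in range(1, max_p + 1):
        y, x = _lag_design(values[max_p - p :], p)  # align effective samples
        t_eff = y.shape[0]
        b, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ b
        sigma_ml = resid.T @ resid / t_eff
        sign, logdet = np.linalg.slogdet(sigma_ml)
        if sign <= 0:
            continue
        n_par = n * (n * p + 1)
        bic = logdet + n_par * np.log(t_eff) / t_eff
        if bic < best_bic:
            best_bic, best_p = bic, p
    return best_p


def ma_coefficients(params: VARParams | np.ndarray, horizon: int) -> np.ndarray:
    """Moving-average matrices Psi_0..Psi_horizon of a VAR(p).

    Psi_0 = I and Psi_h = sum_{j=1..min(h,p)} A_j Psi_{h-j}.  For a VAR(1)
    this is simply Psi_h = A^h.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    coefs = params.coefs if isinstance(params, VARParams) else np.asarray(params, dtype=float)
    p, n, _ = coefs.shape
    psi = np.zeros((horizon + 1, n, n))
    psi[0] = np.eye(n)
    for h in range(1, horizon + 1):
        acc = np.zeros((n, n))
        for j in range(1, min(h, p) + 1):
            acc += coefs[j - 1] @ psi[h - j]
        psi[h] = acc
    return psi


def _psd_guard(m: np.ndarray, label: str, t: int) -> np.ndarray:
    """Symmetrize and, only when a negative diagonal betrays indefiniteness,
    clip eigenvalues at zero with a logged warning."""
    m = 0.5 * (m + m.T)
    if np.min(np.diag(m)) < 0:
        w, v = np.linalg.eigh(m)
        if w[0] < -1e-8 * max(1.0, abs(w[-1])):
            logger.warning("clipped negative eigenvalues of %s at t=%d (min %.3e)", label, t, w[0])
        m = (v * np.clip(w, 0.0, None)) @ v.T
        m = 0.5 * (m + m.T)
    return m


def fit_tvp_var(
    values: np.ndarray,
    p: int,
    kappa1: float = 0.99,
    kappa2: float = 0.96,
    prior: str = "ols",
    prior_fraction: float = 0.1,
    diffuse_scale: float = 1e6,
    store_uncertainty: str = "diag",
) -> list[TVPVARState]:
    """Forward Kalman recursion with forgetting factors.

    Parameters
    ----------
    values : (T, N) array
        The stationary panel; no missing values allowed.
    p : int
        VAR lag order.
    kappa1, kappa2 : float in (0, 1]
        Forgetting factors for the coefficient uncertainty (predictive
        covariance divided by ``kappa1``) and the EWMA innovation covariance.
    prior : {"ols", "diffuse"}
        "ols" initializes from a least-squares fit on the leading
        ``prior_fraction`` of the sample (the filter still runs over every
        period); "diffuse" uses a zero mean with covariance
        ``diffuse_scale * I`` and identity innovation covariance.
    store_uncertainty : {"diag", "full", "none"}
        How much of the posterior coefficient covariance each state keeps.

    Returns one state per usable period t = p..T-1.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a (T, N) array")
    if not np.all(np.isfinite(values)):
        raise ValueError("panel contains non-finite values")
    if not (0.0 < kappa1 <= 1.0 and 0.0 < kappa2 <= 1.0):
        raise ValueError("forgetting factors must lie in (0, 1]")
    if store_uncertainty not in {"diag", "full", "none"}:
        raise ValueError("store_uncertainty must be 'diag', 'full' or 'none'")
    t_total, n = values.shape
    k = n * p + 1
    m = n * k  # stacked state dimension

    y_all, x_all = _lag_design(values, p)
    rows = y_all.shape[0]
    if rows < 1:
        raise ValueError("not enough observations for the requested lag order")

    if prior == "ols":
        n_train = max(int(np.ceil(prior_fraction * rows)), k + 2)
        n_train = min(n_train, rows)
        try:
            init = fit_ols_var(values[: n_train + p], p)
            beta_mat = np.column_stack(
                [init.intercept] + [init.coefs[j] for j in range(p)]
            )  # (N, k) with columns [c, A1, ..., Ap] blocks
            xtx = x_all[:n_train].T @ x_all[:n_train]
            p_cov = np.kron(init.sigma, np.linalg.inv(xtx))
            sigma = init.sigma.copy()
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"training-window OLS prior failed: {exc}") from exc
    elif prior == "diffuse":
        beta_mat = np.zeros((n, k))
        p_cov = diffuse_scale * np.eye(m)
        sigma = np.eye(n)
    else:
        raise ValueError("prior must be 'ols' or 'diffuse'")

    states: list[TVPVARState] = []
    for t in range(rows):
        x_t = x_all[t]
        y_t = y_all[t]
        # prediction: random-walk state, inflated uncertainty
        p_pred = p_cov / kappa1
        # with H = I_N kron x', exploit the block structure:
        # (H P H')_{ab} = x' P[a-block, b-block] x
        p4 = p_pred.reshape(n, k, n, k)
        px = p4 @ x_t  # (n, k, n)
        hph = np.einsum("j,ajb->ab", x_t, px)
        f = 0.5 * (hph + hph.T) + sigma
        err = y_t - beta_mat @ x_t
        try:
            finv_err = np.linalg.solve(f, err)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"singular innovation covariance at period {t + p}") from exc
        beta_mat = beta_mat + np.einsum("b,bak->ak", finv_err, np.transpose(px, (2, 0, 1)))
        # covariance update P = P_pred - (P H') F^-1 (H P_pred)
        hp = np.transpose(px, (2, 0, 1)).reshape(n, m)  # (n, m) rows = H P_pred
        pht = hp.T  # (m, n), symmetric P_pred
        p_cov = p_pred - pht @ np.linalg.solve(f, hp)
        p_cov = _psd_guard(p_cov, "coefficient covariance", t + p)
        # EWMA innovation covariance from the one-step-ahead prediction error
        sigma = kappa2 * sigma + (1.0 - kappa2) * np.outer(err, err)
        sigma = _psd_guard(sigma, "innovation covariance", t + p)

        intercept = beta_mat[:, 0].copy()
        coefs = np.stack([beta_mat[:, 1 + j * n : 1 + (j + 1) * n] for j in range(p)])
        if store_uncertainty == "full":
            unc = p_cov.copy()
        elif store_uncertainty == "diag":
            unc = np.diag(p_cov).copy()
        else:
            unc = np.empty(0)
        states.append(
            TVPVARState(
                t=t + p,
                intercept=intercept,
                coefs=coefs,
                sigma=sigma.copy(),
                uncertainty=unc,
                kappa1=kappa1,
                kappa2=kappa2,
            )
        )
    return states
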