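"""First/second cumulant dynamics, stationary solutions, and correlations.

The occupancy mean and covariance obey exact affine recursions,

    mu_{t+1}    = eps_t + mu_t Q
    Sigma_{t+1} = Delta_t + Lambda_t + Q^T Sigma_t Q

where ``Lambda_t = diag(mu_t Q) - Q^T diag(mu_t) Q`` is the multinomial
redistribution noise.  With a stationary arrival law the fixed points are

    mu_bar    = eps (I - Q)^{-1}
    Sigma_bar = sum_k (Q^T)^k (Delta + Lambda_bar) Q^k,

the latter being the solution of the discrete Stein (Lyapunov) equation
``Sigma = (Delta + Lambda_bar) + Q^T Sigma Q``.  Two-time covariances decay
geometrically: ``Cov(N^t, N^{t+s}) = Sigma_t Q^s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "MomentState",
    "lambda_matrix",
    "mean_step",
    "var_step",
    "stationary_mean",
    "stationary_variance",
    "stationary_variance_series",
    "space_correlations",
    "two_time_cov",
    "normalized_time_corr",
    "propagate",
]


@dataclass
class MomentState:
    """The pair ``(mu_t, Sigma_t)`` at time ``t``."""

    mu: np.ndarray
    sigma: np.ndarray
    t: int = 0


def lambda_matrix(mu, Q) -> np.ndarray:
    """Multinomial redistribution covariance ``Lambda``.

    ``Lambda[i, j] = sum_k mu_k (Q[k, i] delta_ij - Q[k, i] Q[k, j])``,
    i.e. ``diag(mu Q) - Q^T diag(mu) Q``; symmetric positive semidefinite
    for ``mu >= 0``.
    """
    mu = np.asarray(mu, dtype=float)
    Q = np.asarray(Q, dtype=float)
    return np.diag(mu @ Q) - Q.T @ (mu[:, None] * Q)


def mean_step(mu, eps, Q) -> np.ndarray:
    """One step of the mean recursion, ``mu_{t+1} = eps_t + mu_t Q``."""
    return np.asarray(eps, dtype=float) + np.asarray(mu, dtype=float) @ np.asarray(Q)


def var_step(sigma, delta, mu, Q) -> np.ndarray:
    """One step of the covariance recursion,
    ``Sigma_{t+1} = Delta_t + Lambda(mu_t) + Q^T Sigma_t Q``."""
    Q = np.asarray(Q, dtype=float)
    return np.asarray(delta, dtype=float) + lambda_matrix(mu, Q) + Q.T @ np.asarray(sigma) @ Q


def propagate(eps, delta, Q, T: int, state: MomentState | None = None) -> MomentState:
    """Iterate the exact cumulant recursions ``T`` steps from ``state``
    (default: empty system).  ``eps``/``delta`` may be constants or callables
    of ``t`` for time-dependent arrival laws."""
    Q = np.asarray(Q, dtype=float)
    S = Q.shape[0]
    if state is None:
        state = MomentState(mu=np.zeros(S), sigma=np.zeros((S, S)), t=0)
    mu, sigma, t0 = state.mu.copy(), state.sigma.copy(), state.t
    eps_f = eps if callable(eps) else (lambda t: eps)
    delta_f = delta if callable(delta) else (lambda t: delta)
    for t in range(t0, t0 + T):
        sigma = var_step(sigma, delta_f(t), mu, Q)
        mu = mean_step(mu, eps_f(t), Q)
    return MomentState(mu=mu, sigma=sigma, t=t0 + T)


def stationary_mean(eps, Q) -> np.ndarray:
    """Stationary mean occupancy ``mu_bar = eps (I - Q)^{-1}``."""
    Q = np.asarray(Q, dtype=float)
    eps = np.asarray(eps, dtype=float)
    _check_open(Q)
    # mu (I - Q) = eps  <=>  (I - Q)^T mu^T = eps^T
    return np.linalg.solve((np.eye(Q.shape[0]) - Q).T, eps)


def stationary_variance(delta, mu_bar, Q) -> np.ndarray:
    """Stationary occupancy covariance by direct Stein solve.

    Solves ``Sigma = (Delta + Lambda_bar) + Q^T Sigma Q`` exactly (vectorized
    linear solve); robust as ``rho -> 1`` where the series converges slowly.
    """
    Q = np.asarray(Q, dtype=float)
    _check_open(Q)
    M = np.asarray(delta, dtype=float) + lambda_matrix(mu_bar, Q)
    # solve_discrete_lyapunov solves X = A X A^T + Q_ with A = Q^T
    sigma = linalg.solve_discrete_lyapunov(Q.T, M)
    return (sigma + sigma.T) / 2.0


def stationary_variance_series(delta, mu_bar, Q, tol: float = 1e-12) -> np.ndarray:
    """Truncated-series evaluation ``sum_k (Q^T)^k M Q^k`` (cross-check route).

    The truncation index K is chosen by the geometric tail bound
    ``rho^{2K} / (1 - rho^2) * ||M|| < tol``.
    """
    Q = np.asarray(Q, dtype=float)
    rho = _check_open(Q)
    M = np.asarray(delta, dtype=float) + lambda_matrix(mu_bar, Q)
    norm_M = np.linalg.norm(M, ord=np.inf)
    if rho == 0.0 or norm_M == 0.0:
        K = 1
    else:
        K = max(1, math.ceil(math.log(tol * (1 - rho**2) / norm_M) / (2 * math.log(rho))))
    sigma = np.zeros_like(M)
    Qk = np.eye(Q.shape[0])
    for _ in range(K + 1):
        sigma += Qk.T @ M @ Qk
        Qk = Qk @ Q
    return (sigma + sigma.T) / 2.0


def space_correlations(sigma_bar) -> np.ndarray:
    """Equal-time correlation matrix ``kappa[i, j] =
    Sigma[i, j] / sqrt(Sigma[i, i] Sigma[j, j])``."""
    sigma_bar = np.asarray(sigma_bar, dtype=float)
    d = np.sqrt(np.diag(sigma_bar))
    if np.any(d <= 0):
        raise ValueError("correlations require strictly positive variances")
    return sigma_bar / np.outer(d, d)


def two_time_cov(sigma_t, Q, s: int) -> np.ndarray:
    """Lag-``s`` cross-covariance ``Cov(N^t, N^{t+s}) = Sigma_t Q^s``."""
    if s < 0:
        raise ValueError("lag must be nonnegative")
    Q = np.asarray(Q, dtype=float)
    return np.asarray(sigma_t, dtype=float) @ np.linalg.matrix_power(Q, s)


def normalized_time_corr(sigma_bar, Q, s: int) -> np.ndarray:
    """Normalized two-time correlation ``C_tilde(s)``; ``C_tilde(0)`` equals
    the equal-time correlation matrix ``kappa``."""
    sigma_bar = np.asarray(sigma_bar, dtype=float)
    d = np.sqrt(np.diag(sigma_bar))
    if np.any(d <= 0):
        raise ValueError("normalization requires strictly positive variances")
    return two_time_cov(sigma_bar, Q, s) / np.outer(d, d)


def _check_open(Q: np.ndarray) -> float:
    rho = float(np.max(np.abs(np.linalg.eigvals(Q))))
    if rho >= 1.0:
        raise ValueError(f"spectral radius {rho:.15g} >= 1: stationary solution does not exist")
    return rho
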