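"""Forward simulation of the open chain and empirical moment estimators.

One step of the dynamics: every particle at state ``i`` independently picks a
destination among the ``S`` internal states and the exit, with probabilities
``(Q[i, 0], ..., Q[i, S-1], e[i])``, so per-source destination counts are
multinomial; a fresh arrival vector is then drawn from the protocol and added.
Particle number is conserved exactly per realization:
``N^{t+1}.sum() = N^t.sum() - O_t + I_t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import OpenChain
from .protocols import ArrivalProtocol

__all__ = [
    "Trajectory",
    "step",
    "run",
    "default_burn_in",
    "ensemble_moments",
    "stationary_moments",
    "empirical_two_time_cov",
    "empirical_space_corr",
    "empirical_time_corr",
]

#: Occupancies are stored as int64; counts beyond 2**53 would silently lose
#: integer precision in float conversions, so they are an error.
MAX_COUNT = 2**53


@dataclass
class Trajectory:
    """Record of one simulated run.

    ``N`` has shape ``(T+1, S)`` (occupancies, including the initial state),
    ``J`` shape ``(T, S)`` (arrivals), ``O`` and ``I`` length ``T`` (total
    departures and total arrivals per step).
    """

    N: np.ndarray
    J: np.ndarray
    O: np.ndarray
    I: np.ndarray
    seed: int | None
    chain_summary: dict = field(default_factory=dict)
    protocol_spec: dict = field(default_factory=dict)

    @property
    def T(self) -> int:
        return self.N.shape[0] - 1

    @property
    def S(self) -> int:
        return self.N.shape[1]

    def check_conservation(self) -> None:
        """Assert the exact per-step particle balance on every step."""
        lhs = self.N[1:].sum(axis=1)
        rhs = self.N[:-1].sum(axis=1) - self.O + self.I
        if not np.array_equal(lhs, rhs):
            raise AssertionError("particle conservation violated")

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: columns ``t, N_0..N_{S-1}, I, O`` (I, O are NaN at t=0)."""
        T, S = self.T, self.S
        df = pd.DataFrame(self.N, columns=[f"N_{i}" for i in range(S)])
        df.insert(0, "t", np.arange(T + 1))
        df["I"] = np.concatenate([[np.nan], self.I])
        df["O"] = np.concatenate([[np.nan], self.O])
        return df


def step(chain: OpenChain, protocol: ArrivalProtocol, N, rng: np.random.Generator,
         J_step: np.ndarray | None = None):
    """Advance the occupancy vector one time step.

    Returns ``(N_next, O_step, J_step)``: the next occupancy, the number of
    departures this step, and the arrival vector used.  ``J_step`` may be
    supplied (pre-drawn) to allow batched arrival sampling.
    """
    N = np.asarray(N)
    if np.any(N < 0) or not np.issubdtype(N.dtype, np.integer):
        Nf = np.asarray(N, dtype=float)
        if np.any(Nf < 0) or np.any(Nf != np.round(Nf)):
            raise ValueError("occupancy must be a vector of nonnegative integers")
        N = Nf.astype(np.int64)
    if N.max(initial=0) > MAX_COUNT:
        raise OverflowError("occupancy exceeds 2**53")
    S = chain.S
    pvals = np.column_stack([chain.Q, chain.e])
    # one multinomial row per source state; row i redistributes N[i] particles
    A = rng.multinomial(N, pvals)
    R = A[:, :S].sum(axis=0)
    O_step = int(A[:, S].sum())
    assert R.sum() + O_step == N.sum()  # exact multinomial conservation
    if J_step is None:
        J_step = protocol.sample(rng)
    return R + J_step, O_step, J_step


def run(chain: OpenChain, protocol: ArrivalProtocol, N0=None, T: int = 1000,
        seed: int | None = None, rng: np.random.Generator | None = None) -> Trajectory:
    """Simulate ``T`` steps and record the full trajectory.

    Either a ``seed`` (logged in the trajectory) or an explicit generator may
    be passed; arrivals are drawn up front in one batched call where the
    protocol supports it.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    S = chain.S
    if N0 is None:
        N0 = np.zeros(S, dtype=np.int64)
    N0 = np.asarray(N0, dtype=np.int64)
    if N0.shape != (S,) or np.any(N0 < 0):
        raise ValueError("N0 must be a length-S vector of nonnegative integers")

    J = protocol.sample_batch(rng, T).astype(np.int64)
    N = np.empty((T + 1, S), dtype=np.int64)
    O = np.empty(T, dtype=np.int64)
    N[0] = N0
    pvals = np.column_stack([chain.Q, chain.e])
    for t in range(T):
        A = rng.multinomial(N[t], pvals)
        R = A[:, :S].sum(axis=0)
        O[t] = A[:, S].sum()
        N[t + 1] = R + J[t]
    traj = Trajectory(N=N, J=J, O=O, I=J.sum(axis=1), seed=seed,
                      chain_summary=chain.summary(), protocol_spec=protocol.spec())
    traj.check_conservation()
    return traj


def default_burn_in(chain: OpenChain) -> int:
    """Burn-in for stationary estimates: relaxation is geometric at rate rho,
    so ``max(1000, 50 / (1 - rho))`` steps suppress the initial transient."""
    return int(max(1000, math.ceil(50.0 / (1.0 - chain.rho))))


def _stationary_block(traj: Trajectory, burn_in: int) -> np.ndarray:
    if burn_in >= traj.T:
        raise ValueError("burn-in leaves no samples")
    return traj.N[burn_in + 1:]


def ensemble_moments(trajectories, t: int):
    """Cross-replicate sample mean and covariance of ``N^t``.

    Returns ``(mu_hat, sigma_hat, se_mu)`` where ``se_mu`` is the standard
    error of each mean component; covariance uses the n-1 denominator.
    """
    X = np.stack([traj.N[t] for traj in trajectories]).astype(float)
    n = X.shape[0]
    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False).reshape(X.shape[1], X.shape[1])
    se = np.sqrt(np.diag(sigma) / n)
    return mu, sigma, se


def stationary_moments(traj: Trajectory, burn_in: int | None = None, n_batches: int = 50):
    """Time-average stationary mean and covariance from one long run.

    Standard errors of the mean are estimated by batch means (``n_batches``
    contiguous blocks), which absorbs the serial correlation of the chain.
    Returns ``(mu_hat, sigma_hat, se_mu)``.
    """
    if burn_in is None:
        burn_in = default_burn_in_from_summary(traj)
    X = _stationary_block(traj, burn_in).astype(float)
    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False).reshape(X.shape[1], X.shape[1])
    batches = np.array_split(X, n_batches)
    bm = np.stack([b.mean(axis=0) for b in batches])
    se = bm.std(axis=0, ddof=1) / np.sqrt(len(batches))
    return mu, sigma, se


def default_burn_in_from_summary(traj: Trajectory) -> int:
    rho = traj.chain_summary.get("rho", 0.0)
    return int(max(1000, math.ceil(50.0 / (1.0 - rho))))


def empirical_two_time_cov(traj: Trajectory, max_lag: int, burn_in: int | None = None) -> np.ndarray:
    """Stationary lag cross-covariance matrices ``C_hat(s)``, shape
    ``(max_lag+1, S, S)``; ``C_hat(0)`` is the sample covariance.

    ``C_hat(s)[i, j]`` estimates ``Cov(N_i^t, N_j^{t+s})`` by averaging over
    the (single) trajectory after burn-in.
    """
    if burn_in is None:
        burn_in = default_burn_in_from_summary(traj)
    X = _stationary_block(traj, burn_in).astype(float)
    n = X.shape[0]
    if n <= max_lag + 1:
        raise ValueError("trajectory too short for requested max_lag")
    mu = X.mean(axis=0)
    Xc = X - mu
    out = np.empty((max_lag + 1, X.shape[1], X.shape[1]))
    for s in range(max_lag + 1):
        out[s] = Xc[: n - s].T @ Xc[s:] / (n - s - 1)
    return out


def empirical_space_corr(traj: Trajectory, burn_in: int | None = None, n_batches: int = 50):
    """Equal-time correlation matrix ``kappa_hat`` with batch-mean standard errors.

    Returns ``(kappa_hat, se)``; the diagonal is exactly one with zero error.
    """
    if burn_in is None:
        burn_in = default_burn_in_from_summary(traj)
    X = _stationary_block(traj, burn_in).astype(float)
    S = X.shape[1]
    kappa = np.corrcoef(X, rowvar=False).reshape(S, S)
    batches = np.array_split(X, n_batches)
    bk = np.stack([np.corrcoef(b, rowvar=False).reshape(S, S) for b in batches])
    se = bk.std(axis=0, ddof=1) / np.sqrt(len(batches))
    np.fill_diagonal(se, 0.0)
    return kappa, se


def empirical_time_corr(traj: Trajectory, max_lag: int, burn_in: int | None = None,
                        n_batches: int = 50):
    """Normalized two-time correlations ``C_tilde_hat(s)`` with batch-mean errors.

    ``C_tilde(s)[i, j] = Cov(N_i^t, N_j^{t+s}) / sqrt(Var N_i Var N_j)``.
    Returns ``(ctilde, se)``, both of shape ``(max_lag+1, S, S)``.
    """
    if burn_in is None:
        burn_in = default_burn_in_from_summary(traj)
    X = _stationary_block(traj, burn_in).astype(float)
    batches = np.array_split(X, n_batches)
    per_batch = []
    for b in batches:
        per_batch.append(_normalized_lag_corr(b, max_lag))
    bk = np.stack(per_batch)
    ctilde = _normalized_lag_corr(X, max_lag)
    se = bk.std(axis=0, ddof=1) / np.sqrt(len(batches))
    return ctilde, se


def _normalized_lag_corr(X: np.ndarray, max_lag: int) -> np.ndarray:
    n, S = X.shape
    mu = X.mean(axis=0)
    Xc = X - mu
    sd = X.std(axis=0, ddof=1)
    norm = np.outer(sd, sd)
    out = np.empty((max_lag + 1, S, S))
    for s in range(max_lag + 1):
        out[s] = (Xc[: n - s].T @ Xc[s:] / (n - s - 1)) / norm
    return out
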