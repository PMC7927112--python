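"""Brute-force exact evolution of the occupancy pmf for tiny chains.

The occupancy process is a Markov chain on ``N_0^S`` with kernel

    K(k, n) = P(J + R = n),  R | k = sum of per-state multinomial thinnings,

so for small state counts and capped occupancies the pmf can be pushed
forward exactly.  This module is ground truth for the simulator, the m.g.f.
engine and the cumulant recursions on one- and two-state systems.

Truncation policy: the grid caps each component at ``n_max``; probability
mass falling outside the cap is *dropped and tracked* in ``truncation_mass``
(never silently renormalized), and results are flagged invalid when it
exceeds 1e-8.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .chain import OpenChain
from .protocols import ArrivalProtocol

__all__ = ["PMFTable", "exact_kernel", "kernel_matrix", "evolve_pmf",
           "stationary_pmf", "two_time_joint_cov"]

#: hard cap on enumerated grid size (n_max+1)^S
MAX_GRID = 10**6
#: truncation mass above which oracle results are considered invalid
VALID_LEAK = 1e-8


@dataclass
class PMFTable:
    """Exact (truncated) pmf of the occupancy vector on a grid.

    ``probs`` has shape ``(n_max+1,) * S``; ``probs[n]`` is ``P(N = n)``.
    ``truncation_mass`` is the probability assigned outside the cap.
    """

    S: int
    n_max: int
    probs: np.ndarray
    truncation_mass: float = 0.0

    @property
    def valid(self) -> bool:
        return self.truncation_mass < VALID_LEAK

    def grid(self) -> np.ndarray:
        """All occupancy vectors on the grid, shape ``(G, S)``, in C order."""
        axes = [np.arange(self.n_max + 1)] * self.S
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, self.S)

    def mean(self) -> np.ndarray:
        p = self.probs.reshape(-1)
        return p @ self.grid()

    def cov(self) -> np.ndarray:
        p = self.probs.reshape(-1)
        V = self.grid().astype(float)
        m = p @ V
        centered = V - m
        return (centered * p[:, None]).T @ centered

    def mgf(self, alpha) -> float:
        p = self.probs.reshape(-1)
        return float(p @ np.exp(self.grid() @ np.asarray(alpha, dtype=float)))

    def total(self) -> float:
        return float(self.probs.sum())


def _check_grid(S: int, n_max: int) -> None:
    if (n_max + 1) ** S > MAX_GRID:
        raise ValueError(f"grid (n_max+1)^S = {(n_max + 1) ** S} exceeds {MAX_GRID}")


def _arrival_pmf_array(protocol: ArrivalProtocol, n_max: int, tol: float = 1e-14):
    """Arrival pmf on the grid plus the mass lost to truncation."""
    S = protocol.S
    arr = np.zeros((n_max + 1,) * S)
    leak = 0.0
    total = 0.0
    for v, p in protocol.pmf_table(tol):
        total += p
        if np.all(v <= n_max):
            arr[tuple(v)] += p
        else:
            leak += p
    leak += max(0.0, 1.0 - total)  # mass the protocol itself truncated
    return arr, leak


def _redistribution_pmf(chain: OpenChain, i: int, c: int) -> np.ndarray:
    """Pmf of the destination-count vector of ``c`` particles at state ``i``.

    Each particle goes to state ``j`` w.p. ``Q[i, j]`` or exits w.p. ``e_i``;
    the exit count is marginalized out, leaving a multinomial law over
    vectors ``r`` with ``sum(r) <= c`` on a ``(c+1,)*S`` grid.
    """
    S = chain.S
    out = np.zeros((c + 1,) * S)
    q = chain.Q[i]
    e = chain.e[i]
    log_q = np.where(q > 0, np.log(np.where(q > 0, q, 1.0)), -np.inf)
    log_e = np.log(e) if e > 0 else -np.inf
    lgam = [math.lgamma(n + 1) for n in range(c + 1)]
    for r in itertools.product(range(c + 1), repeat=S):
        m = sum(r)
        if m > c:
            continue
        rest = c - m
        if rest > 0 and e == 0.0:
            continue
        logp = lgam[c] - lgam[rest] - sum(lgam[x] for x in r)
        ok = True
        for j, rj in enumerate(r):
            if rj > 0:
                if q[j] == 0.0:
                    ok = False
                    break
                logp += rj * log_q[j]
        if not ok:
            continue
        if rest > 0:
            logp += rest * log_e
        out[r] = math.exp(logp)
    return out


def exact_kernel(chain: OpenChain, protocol: ArrivalProtocol, k, n_max: int):
    """One kernel row: the pmf of ``N^{t+1}`` given ``N^t = k``.

    Returns ``(probs, truncation_mass)`` with ``probs`` on the
    ``(n_max+1,)*S`` grid.  The redistribution law is built by convolving the
    per-source multinomial contributions destination-wise, then convolving
    with the arrival pmf.
    """
    k = np.asarray(k, dtype=np.int64)
    S = chain.S
    _check_grid(S, n_max)
    if np.any(k < 0) or np.any(k > n_max):
        raise ValueError("occupancy k must lie within the grid cap")
    conv = np.ones((1,) * S)
    for i in range(S):
        if k[i] > 0:
            conv = signal.convolve(conv, _redistribution_pmf(chain, i, int(k[i])),
                                   method="direct")
    arrivals, leak = _arrival_pmf_array(protocol, n_max)
    conv = signal.convolve(conv, arrivals, method="direct")
    conv = np.clip(conv, 0.0, None)  # direct convolution can leave -1e-20 dust
    probs = np.zeros((n_max + 1,) * S)
    sl = tuple(slice(0, min(d, n_max + 1)) for d in conv.shape)
    probs[sl] = conv[sl]
    leak += max(0.0, float(conv.sum() - probs.sum()))
    return probs, leak


def kernel_matrix(chain: OpenChain, protocol: ArrivalProtocol, n_max: int):
    """Full transition matrix over the flattened grid.

    Returns ``(K, leak)``: ``K[g, h] = P(next = n_h | now = n_g)`` and the
    per-row truncated mass.  Feasible only for tiny grids (the row count is
    the full grid size).
    """
    S = chain.S
    _check_grid(S, n_max)
    G = (n_max + 1) ** S
    if G > 5000:
        raise ValueError(f"kernel matrix with {G} rows is too large; reduce n_max or S")
    K = np.empty((G, G))
    leak = np.empty(G)
    axes = [range(n_max + 1)] * S
    for g, k in enumerate(itertools.product(*axes)):
        row, row_leak = exact_kernel(chain, protocol, np.array(k), n_max)
        K[g] = row.reshape(-1)
        leak[g] = row_leak
    return K, leak


def _coerce_pmf0(pmf0, S: int, n_max: int):
    """Flatten an initial pmf (PMFTable, grid array, or None = empty system)."""
    if pmf0 is None:
        p = np.zeros((n_max + 1) ** S)
        p[0] = 1.0
        return p, 0.0
    if isinstance(pmf0, PMFTable):
        if pmf0.S != S or pmf0.n_max != n_max:
            raise ValueError("initial PMFTable grid does not match (S, n_max)")
        return pmf0.probs.reshape(-1).copy(), pmf0.truncation_mass
    arr = np.asarray(pmf0, dtype=float)
    if arr.shape != (n_max + 1,) * S:
        raise ValueError(f"initial pmf must have shape {(n_max + 1,) * S}")
    if np.any(arr < 0) or arr.sum() > 1 + 1e-12:
        raise ValueError("initial pmf must be a (sub-)probability array")
    return arr.reshape(-1).copy(), max(0.0, 1.0 - float(arr.sum()))


def evolve_pmf(chain: OpenChain, protocol: ArrivalProtocol, pmf0, T: int,
               n_max: int) -> PMFTable:
    """Exact ``T``-step push-forward of an initial occupancy pmf.

    ``pmf0`` may be a :class:`PMFTable`, a grid-shaped array, or ``None``
    (point mass at the empty configuration).
    """
    S = chain.S
    _check_grid(S, n_max)
    p, leak0 = _coerce_pmf0(pmf0, S, n_max)
    K, leak = kernel_matrix(chain, protocol, n_max)
    lost = leak0
    for _ in range(T):
        lost += float(p @ leak)
        p = p @ K
    return PMFTable(S=S, n_max=n_max, probs=p.reshape((n_max + 1,) * S),
                    truncation_mass=lost)


def stationary_pmf(chain: OpenChain, protocol: ArrivalProtocol, n_max: int,
                   tol: float = 1e-12, max_iter: int = 100_000) -> PMFTable:
    """Iterate the exact kernel to its fixed point.

    Stops when the total-variation change per step drops below ``tol``.
    """
    S = chain.S
    _check_grid(S, n_max)
    K, leak = kernel_matrix(chain, protocol, n_max)
    p = np.zeros((n_max + 1) ** S)
    p[0] = 1.0
    lost = 0.0
    for _ in range(max_iter):
        lost += float(p @ leak)
        p_next = p @ K
        tv = 0.5 * float(np.abs(p_next - p).sum())
        p = p_next
        if tv < tol:
            return PMFTable(S=S, n_max=n_max, probs=p.reshape((n_max + 1,) * S),
                            truncation_mass=lost)
    raise RuntimeError(f"stationary pmf did not converge within {max_iter} iterations")


def two_time_joint_cov(chain: OpenChain, protocol: ArrivalProtocol, s: int,
                       n_max: int) -> np.ndarray:
    """Exact stationary ``Cov(N^t, N^{t+s})`` by kernel-power enumeration.

    ``Cov[i, j] = E[N_i^t N_j^{t+s}] - mu_i mu_j`` with the conditional mean
    of ``N^{t+s}`` computed from the ``s``-th kernel power.  Tiny systems
    only (``S <= 2``).
    """
    if chain.S > 2:
        raise ValueError("exact two-time covariance is enumerated only for S <= 2")
    if s < 0:
        raise ValueError("lag must be nonnegative")
    table = stationary_pmf(chain, protocol, n_max)
    if not table.valid:
        raise RuntimeError(f"truncation mass {table.truncation_mass:.3g} too large")
    p = table.probs.reshape(-1)
    V = table.grid().astype(float)
    mu = p @ V
    K, _ = kernel_matrix(chain, protocol, n_max)
    Ks = np.linalg.matrix_power(K, s)
    cond_mean = Ks @ V  # row g: E[N^{t+s} | N^t = n_g]
    second = (V * p[:, None]).T @ cond_mean
    return second - np.outer(mu, mu)
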