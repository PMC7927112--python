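"""The open Markov chain object: sub-stochastic jump matrix and escape quantities.

An *open* Markov chain is a finite chain whose particles may leave the state
space: the jump matrix ``Q`` is nonnegative with row sums at most one, and the
row deficit ``e_i = 1 - sum_j Q[i, j]`` is the probability that a particle at
state ``i`` escapes to the external reservoir in one step.  Openness (in the
sense that the population cannot grow without bound under bounded immigration)
requires the spectral radius of ``Q`` to be strictly below one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["OpenChain", "make_chain", "spectral_radius", "escape_vector", "escape_matrix"]

#: Tolerance on row sums exceeding one and on the spectral-radius strictness
#: margin.  Moment formulas degrade as rho -> 1, so near-degenerate chains are
#: rejected early.
ROW_SUM_TOL = 1e-12
RHO_MARGIN = 1e-12


@dataclass(frozen=True)
class OpenChain:
    """A validated open Markov chain.

    Attributes
    ----------
    Q : (S, S) ndarray
        Jump probabilities between internal states; ``Q[i, j]`` is the
        probability that a particle at state ``i`` moves to state ``j``.
    e : (S,) ndarray
        Escape probabilities, ``e[i] = 1 - Q[i].sum()``.
    rho : float
        Spectral radius of ``Q``; strictly below one for a valid chain.
    """

    Q: np.ndarray
    e: np.ndarray
    rho: float

    @property
    def S(self) -> int:
        """Number of internal states."""
        return self.Q.shape[0]

    @property
    def E(self) -> np.ndarray:
        """Diagonal escape matrix ``diag(e)``."""
        return np.diag(self.e)

    def fundamental_matrix(self) -> np.ndarray:
        """``(I - Q)^{-1} = sum_k Q^k``, the expected visit-count matrix."""
        return np.linalg.inv(np.eye(self.S) - self.Q)

    def summary(self) -> dict:
        """JSON-serializable summary of the chain."""
        return {
            "S": self.S,
            "row_sums": self.Q.sum(axis=1).tolist(),
            "e": self.e.tolist(),
            "rho": float(self.rho),
        }


def spectral_radius(Q: np.ndarray) -> float:
    """Largest eigenvalue modulus of a square matrix."""
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError(f"Q must be square, got shape {Q.shape}")
    return float(np.max(np.abs(np.linalg.eigvals(Q))))


def make_chain(Q) -> OpenChain:
    """Validate a jump matrix and build an :class:`OpenChain`.

    Parameters
    ----------
    Q : array-like, shape (S, S)
        Nonnegative matrix with row sums <= 1 and spectral radius < 1.

    Raises
    ------
    ValueError
        On negative entries, a row sum exceeding one, or spectral radius at
        (or numerically indistinguishable from) one.

    Warns
    -----
    UserWarning
        If ``Q`` is reducible or periodic.  The classical ergodicity argument
        assumes irreducible aperiodic chains, but every moment formula in this
        package needs only ``rho < 1``, so this is not an error (a ring chain,
        e.g., may be periodic in its internal cycle yet perfectly well-posed).
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError(f"Q must be a square matrix, got shape {Q.shape}")
    if not np.all(np.isfinite(Q)):
        raise ValueError("Q must have finite entries")
    if np.any(Q < 0):
        raise ValueError("Q must be nonnegative")
    row_sums = Q.sum(axis=1)
    if np.any(row_sums > 1.0 + ROW_SUM_TOL):
        bad = int(np.argmax(row_sums))
        raise ValueError(f"row {bad} of Q sums to {row_sums[bad]:.15g} > 1")
    rho = spectral_radius(Q)
    if rho >= 1.0 - RHO_MARGIN:
        raise ValueError(f"not an open chain: spectral radius {rho:.15g} is not strictly below 1")

    _warn_if_not_ergodic(Q)

    e = 1.0 - row_sums
    # exact clip: row sums within ROW_SUM_TOL above 1 give tiny negative e
    e[e < 0] = 0.0
    Q = Q.copy()
    Q.setflags(write=False)
    e.setflags(write=False)
    return OpenChain(Q=Q, e=e, rho=rho)


def _warn_if_not_ergodic(Q: np.ndarray) -> None:
    g = nx.from_numpy_array(np.asarray(Q > 0, dtype=int), create_using=nx.DiGraph)
    if not nx.is_strongly_connected(g):
        warnings.warn("jump matrix is reducible; moment formulas remain valid (rho < 1)")
    elif not nx.is_aperiodic(g):
        warnings.warn("jump matrix is periodic; moment formulas remain valid (rho < 1)")


def escape_vector(chain: OpenChain) -> np.ndarray:
    """Escape probabilities ``e_i = 1 - sum_j Q[i, j]``."""
    return chain.e


def escape_matrix(chain: OpenChain) -> np.ndarray:
    """Diagonal escape matrix ``E = diag(e)``."""
    return chain.E
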