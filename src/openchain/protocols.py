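"""Immigration laws: samplers, exact moments and m.g.f.s of the arrival vector.

Each time step a random nonnegative-integer vector ``J^t`` of new particles
arrives (component ``i`` lands on state ``i``).  A protocol object bundles

* ``sample`` / ``sample_batch`` — draw arrival vectors,
* ``mean`` / ``cov`` — the exact first two moments (``eps`` and ``Delta``),
* ``mgf`` — the moment generating function ``F(alpha) = E[exp(J . alpha)]``,
* ``pmf_table`` — the (possibly truncated) finite support, used by the exact
  enumeration oracle.

Built-in families are i.i.d. in time.  Time-correlated arrival streams can be
plugged in through :class:`HookedProtocol`, which keeps the single-step
marginal moments of a base protocol but delegates sampling to a user-supplied
stateful hook.
"""

from __future__ import annotations

import itertools
from abc import ABC, abstractmethod
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ArrivalProtocol",
    "ConstantProtocol",
    "BernoulliProductProtocol",
    "PoissonProductProtocol",
    "TabularProtocol",
    "HookedProtocol",
    "constant_protocol",
    "bernoulli_product_protocol",
    "poisson_product_protocol",
    "joint_pmf_protocol",
    "paired_bernoulli_protocol",
]


class ArrivalProtocol(ABC):
    """Abstract immigration law for the arrival vector ``J^t``."""

    S: int
    kind: str = "abstract"
    #: True when mean/cov/mgf do not depend on t (all built-ins).
    stationary: bool = True

    @abstractmethod
    def mean(self, t: int | None = None) -> np.ndarray:
        """Arrival mean vector ``eps`` (particles per step)."""

    @abstractmethod
    def cov(self, t: int | None = None) -> np.ndarray:
        """Arrival covariance matrix ``Delta``."""

    @abstractmethod
    def mgf(self, alpha, t: int | None = None):
        """``F(alpha) = E[exp(J . alpha)]`` for a length-S vector ``alpha``."""

    @abstractmethod
    def sample(self, rng: np.random.Generator, t: int | None = None) -> np.ndarray:
        """Draw one arrival vector (length-S nonnegative integers)."""

    def sample_batch(self, rng: np.random.Generator, T: int) -> np.ndarray:
        """Draw ``T`` arrival vectors, shape ``(T, S)``.  Overridden by
        families with a vectorized draw."""
        return np.stack([self.sample(rng) for _ in range(T)])

    def pmf_table(self, tol: float = 1e-14) -> list[tuple[np.ndarray, float]]:
        """Finite support as ``(vector, probability)`` pairs.

        Families with unbounded support truncate, dropping total mass at most
        ``tol``; the returned probabilities then sum to ``1 - leak``.
        """
        raise NotImplementedError(f"{self.kind} protocol has no enumerable support")

    def spec(self) -> dict:
        """JSON-serializable description."""
        return {"type": self.kind}


class ConstantProtocol(ArrivalProtocol):
    """Deterministic arrivals: the same vector ``J0`` every step."""

    kind = "constant"

    def __init__(self, J0):
        J0 = np.atleast_1d(np.asarray(J0, dtype=float))
        if J0.ndim != 1 or np.any(J0 < 0) or np.any(J0 != np.round(J0)):
            raise ValueError("J0 must be a vector of nonnegative integers")
        self.J0 = J0.astype(np.int64)
        self.S = self.J0.size

    def mean(self, t=None):
        return self.J0.astype(float)

    def cov(self, t=None):
        return np.zeros((self.S, self.S))

    def mgf(self, alpha, t=None):
        return np.exp(np.asarray(alpha) @ self.J0)

    def sample(self, rng, t=None):
        return self.J0.copy()

    def sample_batch(self, rng, T):
        return np.tile(self.J0, (T, 1))

    def pmf_table(self, tol=1e-14):
        return [(self.J0.copy(), 1.0)]

    def spec(self):
        return {"type": self.kind, "J0": self.J0.tolist()}


class BernoulliProductProtocol(ArrivalProtocol):
    """Independent Bernoulli(``p_i``) arrivals per state."""

    kind = "bernoulli"

    def __init__(self, p):
        p = np.asarray(p, dtype=float)
        if p.ndim != 1 or np.any(p < 0) or np.any(p > 1):
            raise ValueError("p must be a vector of probabilities in [0, 1]")
        self.p = p
        self.S = p.size

    def mean(self, t=None):
        return self.p.copy()

    def cov(self, t=None):
        return np.diag(self.p * (1.0 - self.p))

    def mgf(self, alpha, t=None):
        return np.prod(1.0 - self.p + self.p * np.exp(np.asarray(alpha)))

    def sample(self, rng, t=None):
        return (rng.random(self.S) < self.p).astype(np.int64)

    def sample_batch(self, rng, T):
        return (rng.random((T, self.S)) < self.p).astype(np.int64)

    def pmf_table(self, tol=1e-14):
        free = np.flatnonzero((self.p > 0) & (self.p < 1))
        if free.size > 20:
            raise NotImplementedError("support too large to enumerate")
        base = (self.p >= 1).astype(np.int64)
        table = []
        for bits in itertools.product((0, 1), repeat=free.size):
            v = base.copy()
            v[free] = bits
            prob = float(np.prod(np.where(v[free] == 1, self.p[free], 1.0 - self.p[free])))
            table.append((v, prob))
        return table

    def spec(self):
        return {"type": self.kind, "p": self.p.tolist()}


class PoissonProductProtocol(ArrivalProtocol):
    """Independent Poisson(``lam_i``) arrivals per state.

    Under Poisson arrivals the stationary occupancy law is product-Poisson
    with mean ``mu_bar`` (the open-network analogue of the infinite-server
    product form), which makes this family a sharp analytic test case.
    """

    kind = "poisson"

    def __init__(self, lam):
        lam = np.asarray(lam, dtype=float)
        if lam.ndim != 1 or np.any(lam < 0):
            raise ValueError("lam must be a vector of nonnegative rates")
        self.lam = lam
        self.S = lam.size

    def mean(self, t=None):
        return self.lam.copy()

    def cov(self, t=None):
        return np.diag(self.lam)

    def mgf(self, alpha, t=None):
        return np.exp(np.sum(self.lam * (np.exp(np.asarray(alpha)) - 1.0)))

    def sample(self, rng, t=None):
        return rng.poisson(self.lam).astype(np.int64)

    def sample_batch(self, rng, T):
        return rng.poisson(self.lam, size=(T, self.S)).astype(np.int64)

    def pmf_table(self, tol=1e-14):
        per_comp = []
        for lam in self.lam:
            if lam == 0:
                per_comp.append([(0, 1.0)])
                continue
            n_hi = int(stats.poisson.isf(tol / max(self.S, 1), lam)) + 1
            pmf = stats.poisson.pmf(np.arange(n_hi + 1), lam)
            per_comp.append(list(enumerate(pmf)))
        table = []
        for combo in itertools.product(*per_comp):
            v = np.array([c[0] for c in combo], dtype=np.int64)
            prob = float(np.prod([c[1] for c in combo]))
            if prob > 0:
                table.append((v, prob))
        return table

    def spec(self):
        return {"type": self.kind, "lam": self.lam.tolist()}


class TabularProtocol(ArrivalProtocol):
    """Arrival law given by an explicit joint pmf table.

    Moments are computed by enumeration; sampling is inverse-CDF over rows.
    """

    kind = "table"

    def __init__(self, table: Sequence[tuple]):
        if len(table) == 0:
            raise ValueError("pmf table is empty")
        vectors = np.asarray([np.asarray(v) for v, _ in table])
        probs = np.asarray([float(p) for _, p in table])
        if vectors.ndim != 2:
            raise ValueError("pmf table vectors must all have the same length")
        if np.any(vectors < 0) or np.any(vectors != np.round(vectors)):
            raise ValueError("pmf table vectors must be nonnegative integers")
        if np.any(probs < 0):
            raise ValueError("pmf table probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"pmf table probabilities sum to {probs.sum():.15g}, not 1")
        self.vectors = vectors.astype(np.int64)
        self.probs = probs / probs.sum()  # remove <=1e-12 float slack only
        self.S = self.vectors.shape[1]

    def mean(self, t=None):
        return self.probs @ self.vectors

    def cov(self, t=None):
        m = self.mean()
        centered = self.vectors - m
        c = (centered * self.probs[:, None]).T @ centered
        return (c + c.T) / 2.0  # exact symmetry despite float summation order

    def mgf(self, alpha, t=None):
        return np.sum(self.probs * np.exp(self.vectors @ np.asarray(alpha)))

    def sample(self, rng, t=None):
        return self.vectors[rng.choice(len(self.probs), p=self.probs)].copy()

    def sample_batch(self, rng, T):
        idx = rng.choice(len(self.probs), size=T, p=self.probs)
        return self.vectors[idx]

    def pmf_table(self, tol=1e-14):
        return [(v.copy(), float(p)) for v, p in zip(self.vectors, self.probs)]

    def spec(self):
        return {
            "type": self.kind,
            "table": [[v.tolist(), float(p)] for v, p in zip(self.vectors, self.probs)],
        }


class HookedProtocol(ArrivalProtocol):
    """Stateful-sampler hook for time-correlated arrival streams.

    Wraps a base protocol whose single-step marginal moments are kept, while
    sampling is delegated to ``hook(rng, t)``, which may carry its own state
    across calls.  The analytic engines use only the marginal moments; the
    stationary two-time occupancy covariance is insensitive to arrival
    autocorrelation, so the built-in i.i.d. families cover the analytics and
    this hook exists for simulation experiments.
    """

    kind = "hooked"
    stationary = True

    def __init__(self, base: ArrivalProtocol, hook: Callable[[np.random.Generator, int], np.ndarray]):
        self.base = base
        self.hook = hook
        self.S = base.S

    def mean(self, t=None):
        return self.base.mean(t)

    def cov(self, t=None):
        return self.base.cov(t)

    def mgf(self, alpha, t=None):
        return self.base.mgf(alpha, t)

    def sample(self, rng, t=None):
        j = np.asarray(self.hook(rng, 0 if t is None else t), dtype=np.int64)
        if j.shape != (self.S,) or np.any(j < 0):
            raise ValueError("hook must return a length-S nonnegative integer vector")
        return j

    def sample_batch(self, rng, T):
        return np.stack([self.sample(rng, t) for t in range(T)])


def constant_protocol(J0) -> ConstantProtocol:
    """Degenerate arrivals: exactly ``J0`` particles per step."""
    return ConstantProtocol(J0)


def bernoulli_product_protocol(p) -> BernoulliProductProtocol:
    """Independent Bernoulli(``p_i``) arrivals."""
    return BernoulliProductProtocol(p)


def poisson_product_protocol(lam) -> PoissonProductProtocol:
    """Independent Poisson(``lam_i``) arrivals."""
    return PoissonProductProtocol(lam)


def joint_pmf_protocol(table) -> TabularProtocol:
    """Arrival law from an explicit ``(vector, probability)`` table."""
    return TabularProtocol(table)


def paired_bernoulli_protocol(p: float) -> TabularProtocol:
    """Three-state arrival law with a tunable pair dependence.

    ``(J_1, J_2)`` are marginally Bernoulli(1/2) with joint law

    ====== ==========
    (1, 1)  p/2
    (0, 0)  p/2
    (1, 0)  (1-p)/2
    (0, 1)  (1-p)/2
    ====== ==========

    and ``J_3`` is an independent Bernoulli(1/2).  The parameter ``p`` moves
    the pair correlation through ``Cov(J_1, J_2) = (2p - 1)/4``: independent
    at ``p = 1/2``, comonotone at ``p = 1``, antithetic at ``p = 0``.  The
    marginal mean is ``(1/2, 1/2, 1/2)`` for every ``p``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    pair = {(1, 1): p / 2, (0, 0): p / 2, (1, 0): (1 - p) / 2, (0, 1): (1 - p) / 2}
    table = []
    for (j1, j2), q12 in pair.items():
        for j3 in (0, 1):
            if q12 > 0:
                table.append((np.array([j1, j2, j3]), q12 * 0.5))
    proto = TabularProtocol(table)
    proto.kind = "paired_bernoulli"
    proto._p = p
    proto.spec = lambda: {"type": "paired_bernoulli", "p": p}  # type: ignore[method-assign]
    return proto
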