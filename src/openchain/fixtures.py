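"""Canonical worked-example systems with their known closed forms.

These small open chains have exact stationary moments expressible in the
parameters, which makes them the reference cases for cross-validating the
m.g.f. engine, the cumulant recursions, the enumeration oracle and the
simulator:

* ``one_vertex(p, q)`` — a single state with Bernoulli(p) arrivals and
  retention probability q.  Stationary occupancy is the infinite convolution
  of Bernoulli(p q^r) laws: mean ``p/(1-q)``, variance
  ``p/(1-q) - p^2/(1-q^2)``.
* ``ring(L, q, a, b, p)`` — a biased walk on Z/LZ, open only at site 0.
* ``triangle(p, q)`` — three fully-connected states with
  ``Q = q (J - I)`` and the correlated-pair arrival law
  (:func:`~openchain.protocols.paired_bernoulli_protocol`); stationary mean
  is ``1/(2-4q)`` per state and ``Q^k`` has an explicit spectral form.
* ``mixed_exit(p1, p3)`` — a three-state chain whose rows leak differently
  (escape vector ``(1/4, 1/2, 0)``), with Bernoulli arrivals at two states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import OpenChain, make_chain
from .protocols import (ArrivalProtocol, bernoulli_product_protocol,
                        paired_bernoulli_protocol)

__all__ = ["FixtureSpec", "one_vertex", "ring", "triangle", "triangle_Qk",
           "mixed_exit", "FIXTURES", "one_vertex_stationary_pmf"]


@dataclass
class FixtureSpec:
    """A named chain + protocol pair with attached closed forms."""

    name: str
    params: dict
    chain: OpenChain
    protocol: ArrivalProtocol
    closed_forms: dict = field(default_factory=dict)

    def config(self) -> dict:
        """Config dict consumable by the CLI (simulate/analyze/correlate)."""
        return {
            "Q": self.chain.Q.tolist(),
            "protocol": self.protocol.spec(),
            "fixture": {"name": self.name, "params": self.params},
        }


def one_vertex(p: float, q: float) -> FixtureSpec:
    """Single-state chain, Bernoulli(p) arrivals, retention q."""
    if not 0.0 <= q < 1.0:
        raise ValueError("one_vertex requires 0 <= q < 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("one_vertex requires 0 <= p <= 1")
    chain = make_chain([[q]])
    proto = bernoulli_product_protocol([p])
    mu = p / (1.0 - q)
    var = p / (1.0 - q) - p**2 / (1.0 - q**2)
    cf = {
        "mu_bar": np.array([mu]),
        "sigma_bar": np.array([[var]]),
        # stationary occupancy = convolution of Bernoulli(p q^r), r = 0, 1, ...
        "bernoulli_factors": lambda r: p * q**r,
        "H_iterate": lambda alpha, r: np.log(1.0 - q**r + q**r * np.exp(alpha)),
        "mean_outflow": p,
        # thinned factors Bernoulli(p q^r (1-q)) give the outflow variance
        "var_outflow": p - p**2 * (1.0 - q) ** 2 / (1.0 - q**2),
    }
    return FixtureSpec("one_vertex", {"p": p, "q": q}, chain, proto, cf)


def one_vertex_stationary_pmf(p: float, q: float, tol: float = 1e-14) -> np.ndarray:
    """Stationary occupancy pmf of the one-vertex chain by direct convolution
    of its Bernoulli(p q^r) factors (factors with ``p q^r < tol`` dropped).

    Independent route from the kernel iteration: the infinite-product m.g.f.
    is the m.g.f. of this convolution.
    """
    pmf = np.array([1.0])
    r = 0
    while True:
        w = p * q**r
        if w < tol:
            return pmf
        pmf = np.convolve(pmf, [1.0 - w, w])
        r += 1
        if r > 10_000:  # q -> 1 guard; unreachable for valid fixtures
            return pmf


def ring(L: int, q: float, a: float, b: float, p: float) -> FixtureSpec:
    """Biased random walk on the ring Z/LZ, open only at site 0.

    Interior site ``i`` jumps to ``i+1 (mod L)`` w.p. ``q`` and to
    ``i-1 (mod L)`` w.p. ``1-q``.  Site 0 jumps to 1 w.p. ``a``, to ``L-1``
    w.p. ``b``, and exits w.p. ``1-a-b``.  Arrivals are Bernoulli(p) at
    site 0 only.
    """
    if L < 2:
        raise ValueError("ring requires L >= 2")
    if not 0.0 < q < 1.0:
        raise ValueError("ring requires 0 < q < 1")
    if a < 0 or b < 0 or not 0.0 < a + b < 1.0:
        raise ValueError("ring requires 0 < a + b < 1")
    Q = np.zeros((L, L))
    Q[0, 1 % L] += a
    Q[0, (L - 1) % L] += b
    for i in range(1, L):
        Q[i, (i + 1) % L] += q
        Q[i, (i - 1) % L] += 1.0 - q
    chain = make_chain(Q)
    pvec = np.zeros(L)
    pvec[0] = p
    proto = bernoulli_product_protocol(pvec)

    def mean_profile(t: int) -> np.ndarray:
        # mu_t = sum_{r < t} eps Q^r, eps = (p, 0, ..., 0)
        mu = np.zeros(L)
        eps = pvec.copy()
        for _ in range(t):
            mu = eps + mu @ Q
        return mu

    cf = {"mean_profile": mean_profile}
    return FixtureSpec("ring", {"L": L, "q": q, "a": a, "b": b, "p": p}, chain, proto, cf)


def triangle(p: float, q: float) -> FixtureSpec:
    """Fully-connected three-state chain ``Q = q (J - I)`` with the
    correlated-pair arrival law.

    Requires ``0 < q < 1/2`` (the spectral radius is ``2q``).  The arrival
    parameter ``p`` sets the dependence between the first two arrival
    components; the marginal arrival mean is ``(1/2, 1/2, 1/2)`` regardless.
    Stationary mean occupancy is ``1/(2 - 4q)`` per state.
    """
    if not 0.0 < q < 0.5:
        raise ValueError("triangle requires 0 < q < 1/2")
    J = np.ones((3, 3))
    chain = make_chain(q * (J - np.eye(3)))
    proto = paired_bernoulli_protocol(p)
    mu = 1.0 / (2.0 - 4.0 * q)
    cf = {
        "mu_bar": np.full(3, mu),
        "Qk": lambda k: triangle_Qk(q, k),
    }
    return FixtureSpec("triangle", {"p": p, "q": q}, chain, proto, cf)


def triangle_Qk(q: float, k: int) -> np.ndarray:
    """Closed form for ``Q^k`` of the triangle chain.

    ``(J - I)`` has eigenvalues ``{2, -1, -1}``, giving
    ``Q^k = (q^k / 3) [ (2^k + 2 (-1)^k) I + (2^k - (-1)^k) (J - I) ]``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    diag = (2.0**k + 2.0 * (-1.0) ** k) / 3.0
    off = (2.0**k - (-1.0) ** k) / 3.0
    M = np.full((3, 3), off)
    np.fill_diagonal(M, diag)
    return q**k * M


def mixed_exit(p1: float = 0.1, p3: float = 0.6) -> FixtureSpec:
    """Three-state chain with heterogeneous leakage.

    Row sums are (3/4, 1/2, 1): the escape vector is ``(1/4, 1/2, 0)`` —
    state 2 (0-based) never loses particles directly.  Arrivals are
    independent Bernoulli at states 0 and 2 with rates ``p1`` and ``p3``.
    """
    Q = np.array([
        [0.0, 0.5, 0.25],
        [0.25, 0.0, 0.25],
        [0.5, 0.25, 0.25],
    ])
    chain = make_chain(Q)
    proto = bernoulli_product_protocol([p1, 0.0, p3])
    cf = {"e": np.array([0.25, 0.5, 0.0])}
    return FixtureSpec("mixed_exit", {"p1": p1, "p3": p3}, chain, proto, cf)


#: registry used by the CLI `examples` subcommand
FIXTURES = {
    "one_vertex": (one_vertex, {"p": 0.5, "q": 0.5}),
    "ring": (ring, {"L": 6, "q": 0.6, "a": 0.35, "b": 0.35, "p": 0.5}),
    "triangle": (triangle, {"p": 0.40, "q": 0.45}),
    "mixed_exit": (mixed_exit, {"p1": 0.1, "p3": 0.6}),
}
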