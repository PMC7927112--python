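"""Statistics of particles leaving the chain (binomial thinning of occupancy).

Departures from state ``i`` at time ``t`` are ``U_i^t ~ Binomial(N_i^t, e_i)``
— a binomial thinning of the occupancy by the escape probabilities — and the
total outflow is ``O_t = sum_i U_i^t``.  The outflow m.g.f. is the occupancy
m.g.f. composed with the componentwise C-map

    C_i(alpha_i) = log(1 - e_i + e_i exp(alpha_i)),

from which the moment formulas follow:

    E[U^t]   = mu_t E,
    Var(U^t) = E Sigma_t E + D_t,   D_t = diag(mu_i e_i (1 - e_i)),
    E[O_t]   = mu_t e^T,
    Var(O_t) = e Sigma_t e^T + mu_t (I - E) e^T.

At stationarity the mean outflow balances the mean inflow exactly:
``mu_bar e^T = sum_i eps_i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import OpenChain
from .mgf import MGFContext, log_mgf_G_stat, mgf_G_t

__all__ = ["OutflowMoments", "c_map", "outflow_mgf", "outflow_moments",
           "stationary_flux_balance"]


@dataclass
class OutflowMoments:
    """Exact first two moments of per-state (``U``) and total (``O``) outflow."""

    mean_U: np.ndarray
    var_U: np.ndarray
    mean_O: float
    var_O: float
    D: np.ndarray

    def summary(self) -> dict:
        return {
            "mean_U": self.mean_U.tolist(),
            "var_U": self.var_U.tolist(),
            "mean_O": float(self.mean_O),
            "var_O": float(self.var_O),
        }


def c_map(chain: OpenChain, alpha) -> np.ndarray:
    """Componentwise thinning map
    ``C_i(alpha_i) = log(1 - e_i + e_i exp(alpha_i))``; ``C(0) = 0``."""
    alpha = np.asarray(alpha, dtype=float)
    return np.log(1.0 - chain.e + chain.e * np.exp(alpha))


def outflow_mgf(ctx: MGFContext, alpha, t: int | None = None) -> float:
    """M.g.f. of the departing vector ``U^t``: ``R_t(alpha) = G_t(C(alpha))``.

    ``t=None`` gives the stationary outflow m.g.f.
    """
    calpha = c_map(ctx.chain, alpha)
    if t is None:
        logG, _ = log_mgf_G_stat(ctx, calpha)
        return float(np.exp(logG))
    return mgf_G_t(ctx, calpha, t)


def outflow_moments(mu, sigma, chain: OpenChain) -> OutflowMoments:
    """Exact outflow moments from the occupancy moments ``(mu, Sigma)``."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    e = chain.e
    E = chain.E
    D = np.diag(mu * e * (1.0 - e))
    var_U = E @ sigma @ E + D
    mean_O = float(mu @ e)
    var_O = float(e @ sigma @ e + mu @ ((1.0 - e) * e))
    return OutflowMoments(mean_U=mu * e, var_U=var_U, mean_O=mean_O, var_O=var_O, D=D)


def stationary_flux_balance(eps, mu_bar, chain: OpenChain, tol: float = 1e-10) -> dict:
    """Check the stationary particle balance ``mu_bar e^T = sum_i eps_i``.

    Returns both sides and their difference; raises if the identity fails
    beyond ``tol`` (which signals an inconsistent ``(eps, mu_bar)`` pair).
    """
    eps = np.asarray(eps, dtype=float)
    mu_bar = np.asarray(mu_bar, dtype=float)
    outflow = float(mu_bar @ chain.e)
    inflow = float(eps.sum())
    gap = abs(outflow - inflow)
    if gap > tol * max(1.0, abs(inflow)):
        raise AssertionError(
            f"stationary flux imbalance: outflow {outflow:.15g} vs inflow {inflow:.15g}")
    return {"mean_outflow": outflow, "mean_inflow": inflow, "gap": gap}
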