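# openchain

Simulation and exact moment analytics for **open Markov chains**: populations
of non-interacting particles that hop on a finite state space, leave it, and
are replenished from outside.

Models of this kind describe patient flow through hospital wards, manpower
and enrollment systems, credit portfolios, compartmental epidemic bookkeeping
and tracer dynamics — any setting where individuals enter a network of
states, move stochastically, and eventually exit.

## The model

A system is specified by a **jump matrix** `Q` (nonnegative, row sums ≤ 1,
spectral radius ρ < 1) and an **arrival protocol** `{Jᵗ}`. Each time step:

1. every particle at state *i* independently jumps to state *j* with
   probability `q_ij` or leaves to the reservoir with the *escape
   probability* `e_i = 1 − Σ_j q_ij` — so per-source destination counts are
   multinomial;
2. a fresh arrival vector `Jᵗ` (mean ε, covariance Δ) is added.

The occupancy vector `Nᵗ` then satisfies exact cumulant recursions

```
μ_{t+1} = ε + μ_t Q
Σ_{t+1} = Δ + Λ_t + Qᵀ Σ_t Q,     Λ_t = diag(μ_t Q) − Qᵀ diag(μ_t) Q
```

with stationary solutions `μ̄ = ε (I − Q)⁻¹` and the discrete Stein
(Lyapunov) equation `Σ̄ = Δ + Λ̄ + Qᵀ Σ̄ Q`. Independently, the m.g.f. of
`Nᵗ` obeys a transfer recursion through the H-map
`H_i(α) = log(e_i + Σ_j q_ij e^{α_j})`, whose stationary limit is the
infinite product `G_stat(α) = Π_r F(H⁽ʳ⁾(α))`. Departures are binomial
thinnings `U_iᵗ ~ Binom(N_iᵗ, e_i)` with
`E[O_t] = μ_t eᵀ`, `Var(O_t) = e Σ_t eᵀ + μ_t (I − E) eᵀ`, and two-time
covariances decay geometrically: `Cov(Nᵗ, Nᵗ⁺ˢ) = Σ_t Qˢ`.

The package computes all of these along three mutually validating routes —
cumulant recursions/Stein solves, m.g.f. differentiation, and (for tiny
chains) exact pmf enumeration — plus an exact stochastic simulator with
Monte-Carlo error bars.

## Worked example

A three-state chain in which state 1 leaks with probability 1/4, state 2
with 1/2, and state 3 is internally closed; Bernoulli arrivals hit states 1
and 3:

```python
import numpy as np
from openchain import make_chain, bernoulli_product_protocol, run
from openchain.cumulants import stationary_mean, stationary_variance, space_correlations
from openchain.outflow import outflow_moments
from openchain.simulator import stationary_moments

chain = make_chain([[0.0, 0.5, 0.25],
                    [0.25, 0.0, 0.25],
                    [0.5, 0.25, 0.25]])
print("escape probabilities:", chain.e, " spectral radius: %.3f" % chain.rho)

protocol = bernoulli_product_protocol([0.1, 0.0, 0.6])
mu = stationary_mean(protocol.mean(), chain.Q)
sigma = stationary_variance(protocol.cov(), mu, chain.Q)
print("stationary mean occupancy:", mu.round(4))
print("spatial correlations:\n", space_correlations(sigma).round(3))
of = outflow_moments(mu, sigma, chain)
print("mean outflow per step: %.4f (inflow %.4f)" % (of.mean_O, protocol.mean().sum()))

traj = run(chain, protocol, T=100_000, seed=0)
mu_hat, _, se = stationary_moments(traj, burn_in=1000)
print("simulated mean:", mu_hat.round(4), "+-", (4 * se).round(4))
```

prints

```
escape probabilities: [0.25 0.5  0.  ]  spectral radius: 0.750
stationary mean occupancy: [1.04 0.88 1.44]
spatial correlations:
 [[ 1.    -0.111 -0.097]
 [-0.111  1.    -0.088]
 [-0.097 -0.088  1.   ]]
mean outflow per step: 0.7000 (inflow 0.7000)
simulated mean: [1.0458 0.888  1.4441] +- [0.015  0.0144 0.0259]
```

Reading: the closed state 3 accumulates the largest mean population; mean
outflow exactly balances mean inflow (0.1 + 0.6 = 0.7); competing occupancy
makes states mildly anticorrelated; and a 10⁵-step simulation reproduces the
exact means within its 4σ Monte-Carlo band.

The same analyses are available from the shell:

```sh
openchain examples emit triangle --out triangle        # write a config
openchain analyze   --config triangle.json             # exact moments
openchain simulate  --config triangle.json --out run   # trajectory + summary
openchain validate  --config triangle.json             # sim-vs-theory z-scores
openchain correlate --config triangle.json --out corr  # two-time correlations
```

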