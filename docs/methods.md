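# Methods

## Model and assumptions

The package implements a discrete-time open population process on a finite
state space of `S` states. Its primitives are:

* **Jump matrix** `Q` (dimensionless probabilities): `q_ij` is the one-step
  probability that a particle at state `i` moves to state `j`. Rows may sum
  to less than one; the deficit `e_i = 1 − Σ_j q_ij` is the per-step escape
  probability to the external reservoir. Validity requires nonnegative
  entries, row sums ≤ 1 (tolerance 1e−12) and spectral radius `ρ(Q) < 1`
  (strictness margin 1e−12). The margin exists because every stationary
  quantity involves resolvent-like objects — `(I − Q)⁻¹`, the Stein
  equation, geometric series in `ρ` — whose conditioning degrades as
  `ρ → 1`, so near-degenerate inputs fail early and loudly.
* **Arrival protocol** `{Jᵗ}` (particles/step): a law for the vector of
  arrivals, exposing exact mean `ε`, covariance `Δ`, m.g.f. `F`, a sampler,
  and (for the enumeration oracle) its finite support. Built-in families —
  constant, product-Bernoulli, product-Poisson, explicit joint pmf table,
  and a three-component law with a tunable dependence between the first two
  components — are i.i.d. in time. Time-correlated streams can be plugged in
  through a stateful sampler hook that keeps the base family's single-step
  marginals; the stationary two-time occupancy covariance `Σ̄ Qˢ` does not
  involve arrival autocorrelation, so the analytic engines need only the
  marginal moments.
* **Dynamics**: per state, destination counts (including exit) are a single
  multinomial draw over `(q_i1, …, q_iS, e_i)`; the redistributed counts
  plus a fresh arrival vector give the next occupancy. Particle number is
  conserved exactly per realization and asserted on every simulated step.

Assumptions: particles are exchangeable and non-interacting; `Q` is constant
in time; classical irreducibility/aperiodicity is *not* required — every
implemented formula needs only `ρ < 1`, so reducible or periodic jump
matrices (e.g. the even-length ring, whose internal cycle has period 2) are
accepted with a warning rather than rejected.

## Analytic engines

**Cumulant recursions.** The mean and covariance of the occupancy evolve
exactly as `μ_{t+1} = ε_t + μ_t Q` and
`Σ_{t+1} = Δ_t + Λ_t + Qᵀ Σ_t Q`, where
`Λ_t = diag(μ_t Q) − Qᵀ diag(μ_t) Q` is the multinomial redistribution
noise (symmetric PSD). Time-dependent `ε_t, Δ_t` are accepted by the
recursions; the stationary solvers require time-invariant inputs.
Stationary mean: linear solve of `μ̄ (I − Q) = ε`. Stationary covariance:
the discrete Stein/Lyapunov equation `Σ̄ = (Δ + Λ̄) + Qᵀ Σ̄ Q`, solved
directly (`scipy.linalg.solve_discrete_lyapunov`), with the truncated series
`Σ_k (Qᵀ)ᵏ (Δ + Λ̄) Qᵏ` retained as an independent cross-check; its
truncation index is set by the tail bound `ρ^{2K}/(1 − ρ²)·‖Δ + Λ̄‖ < 1e−12`.
The direct solve is preferred because it stays accurate as `ρ → 1`, where
the series converges slowly.

A useful analytic fixed point: under independent Poisson arrivals the
stationary law is product-Poisson, `Σ̄ = diag(μ̄)` — the identity
`Δ + Λ̄ + Qᵀ diag(μ̄) Q = diag(λ + μ̄Q) = diag(μ̄)` holds exactly and is
asserted to 1e−12 on random chains in the tests.

**M.g.f. transfer calculus.** The H-map
`H_i(α) = log(e_i + Σ_j q_ij e^{α_j})` propagates m.g.f. arguments backward
one step; its r-th iterate is evaluated through the matrix-power closed form
`H⁽ʳ⁾(α)_i = log(1 − Σ_j (Qʳ)_ij + Σ_j (Qʳ)_ij e^{α_j})` (one log/exp pair,
no accumulation of rounding through composition); naive r-fold composition
is kept purely as a test oracle and agrees to 1e−12. The stationary m.g.f.
is the infinite product `Π_r F(H⁽ʳ⁾(α))`, accumulated in log space.

*Truncation.* The product is cut at the first `r` with `‖Qʳ‖_∞ < tol`
(default 1e−12). This is an α-independent majorant of the natural criterion
`‖H⁽ʳ⁾(α)‖_∞ < tol` (since `‖H⁽ʳ⁾(α)‖_∞ ≤ ‖Qʳ‖_∞ · max_j |e^{α_j} − 1|`).
α-independence matters: a cut index that varies with α introduces
tol-sized discontinuities between the stencil points of finite-difference
differentiation, which second differences amplify by `1/h²`; with a uniform
cut the neglected tail is a smooth function of α with negligible curvature.

*Cumulant extraction.* Means and covariances are read off `log G` by central
finite differences with one Richardson extrapolation step, default step
`h = 1e−3`. With the log-m.g.f. evaluated to ~1e−14 (a few hundred summed
log factors), this balances the `O(h⁴)` extrapolated truncation error
against the `~ε/h²` second-difference roundoff; both land at or below 1e−7
for cumulants of order 1–10. A smaller step would be roundoff-dominated.

**Outflow.** Departures are binomial thinnings; the outflow m.g.f. composes
the occupancy m.g.f. with `C_i(α_i) = log(1 − e_i + e_i e^{α_i})`. Moments:
`E[U] = μE`, `Var(U) = EΣE + diag(μ_i e_i(1 − e_i))`, `E[O] = μeᵀ`,
`Var(O) = eΣeᵀ + μ(I − E)eᵀ`. For the one-vertex chain with Bernoulli(p)
arrivals and retention q these give `E[O] = p` and
`Var(O) = p − p²(1 − q)²/(1 − q²)`. Note the minus sign: the variance of a
sum of independent Bernoulli(w_r) factors is `Σ w_r(1 − w_r)`, *below* the
Poisson-like value `Σ w_r`; the package verifies the closed form against
both the direct factor summation and the Stein route (the corresponding
occupancy variance is likewise `p/(1−q) − p²/(1−q²)`, easy to get wrong by
adding the correction term instead of subtracting it). At stationarity the
flux balance `μ̄eᵀ = Σ_i ε_i` is checked to 1e−10.

**Two-time structure.** `Cov(Nᵗ, Nᵗ⁺ˢ) = Σ_t Qˢ` (stationary: `Σ̄Qˢ`),
normalized entrywise by `√(Σ̄_ii Σ̄_jj)` for the correlation form. In
simulation the estimator averages over a single stationary trajectory
(justified because the stationary quantity depends only on the lag), not
over replicate ensembles.

## Enumeration oracle

For tiny chains the occupancy process is a Markov chain on the integer grid
and its pmf is pushed forward exactly: per-source multinomial destination
laws are convolved destination-wise (direct, not FFT, convolution — exact
sums of products), then convolved with the arrival pmf. The grid caps each
component at `n_max` (guard `(n_max+1)^S ≤ 10⁶`, full transition matrices
only up to 5000 grid points). Mass falling outside the cap is dropped and
*tracked* in `truncation_mass` — never silently renormalized — and results
are flagged invalid above 1e−8. Stationarity is declared when the
total-variation change per sweep falls below 1e−12; since convergence is
geometric at rate ρ, the residual distance to the true fixed point is then
at most `tol/(1 − ρ)`. Exact two-time covariances by kernel powers are
limited to `S ≤ 2`.

## Simulator and estimators

One multinomial draw per source state per step (the independence structure
of the redistribution), batched arrival sampling where the family allows it.
Occupancies are int64 with an error raised beyond 2⁵³ (where float
round-trips would corrupt counts). Burn-in default `max(10³, 50/(1 − ρ))`
steps — relaxation is geometric at rate ρ, so this suppresses the initial
transient by a factor well below statistical resolution. Stationary means,
spatial correlations and lagged correlations carry Monte-Carlo standard
errors estimated by batch means (50 contiguous batches by default), which
absorbs the serial correlation of the chain; validation uses 4σ bands per
statistic (the CLI `validate` report notes the Bonferroni-style familywise
rate).

## Reference systems and what the tests show

The test fixtures are the systems with known closed forms: the one-vertex
chain (stationary law = infinite Bernoulli convolution; mean `p/(1−q)`,
variance `p/(1−q) − p²/(1−q²)`), the open ring (escape only at the origin;
mean profile `Σ_{r<t} εQʳ`), the symmetric triangle `Q = q(J − I)` with
correlated paired arrivals (uniform stationary mean `1/(2−4q)`, spectral
`Qᵏ` closed form, spectral radius `2q < 1`), and a mixed-exit three-state
chain (escape vector `(1/4, 1/2, 0)`). Simulation-consistency checks use
the triangle at `p = 0.40, q = 0.45` with single 5×10⁵-step runs, and the
enumeration-oracle checks use the one-vertex chain at `p = q = 1/2` with
`n_max = 40` — sizes at which the exact engines are numerically tight and a
laptop-scale run resolves all tested statistics well inside 4σ bands.

What passing tests establish: the three independent routes (recursions/Stein,
m.g.f. differentiation, exact enumeration) agree to between 1e−5 and 1e−10
depending on the pair, and the simulator is statistically indistinguishable
from the exact theory on these systems. What they do not establish: behavior
for time-varying jump matrices, interacting particles, heavy-tailed or
batch-arrival laws beyond explicit pmf tables, or continuous-time dynamics —
all outside the model class.

## Degenerate inputs and tie-breaks

* Rows summing to exactly 1 give `e_i = 0`: legal (internally closed state)
  as long as `ρ < 1` overall; a fully stochastic `Q` is rejected.
* Zero rows give `e_i = 1`: the H-map component is identically 0.
* `q = 0` (memoryless): next occupancy equals fresh arrivals; all lagged
  covariances vanish.
* Empty protocols (`p = 0`, `λ = 0`, `J0 = 0`): the empty configuration is
  absorbing and all moments are 0; correlation matrices are undefined
  (zero variance) and raise rather than return NaN.
* States are 0-based internally; distribution vectors are row vectors and
  evolve by right-multiplication with `Q`.

## Known limitations

* Cumulants above order 2 are not computed.
* The enumeration oracle is exponential in `S`; it is deliberately capped.
* The stationary m.g.f. product needs `O(log tol / log ρ)` factors — slow
  (and eventually ill-conditioned) as `ρ → 1`; the Stein route is the
  primary path there.
* The non-stationary two-time theory is limited to `Cov(Nᵗ, Nᵗ⁺ˢ) = Σ_t Qˢ`;
  multi-time joint distributions beyond the two-time case are not exposed.
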