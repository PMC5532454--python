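# Methods

## Model

An SIR epidemic spreads on a configuration-model network of `N`
individuals: degrees are i.i.d. from a pmf `p_k` (or a prescribed
sequence), stubs are paired uniformly at random, and leftover defects
(one odd stub, self-loops, multi-edges) are kept, since they vanish in
density as `N` grows.  Infectives transmit along each susceptible edge
at rate `τ` and recover at rate `γ`, independently; there is no latent
period.

While the infected fraction is small, each transmission almost surely
hits a susceptible, and the infectives form a multitype Markov branching
process indexed by *effective degree* (unpaired stubs).  A type-`k`
individual lives `Exp(ω_k)`, `ω_k = γ + τk`; on death it leaves either
nothing (probability `γ/ω_k`) or the pair `{k−1, L}` with
`L ~ D̃ − 1`, where `D̃` is the size-biased degree
(`p̃_k = k p_k / E[D]`).  Newly infected individuals have type `D̃ − 1`;
only initial infectives can carry the maximal type.  All quantities in
the package are exact properties of this branching process; their value
as epidemic approximations is asymptotic in `N` and does **not** require
many initial infectives.

## Closed forms and the shared limit device

The mean matrix is `M(t) = exp(Ωt)` with
`Ω_{l,k} = τl(p̃_{k+1} + δ_{l,k+1}) − ω_l δ_{l,k}`.  Using
`Ω1 = τn − γ1` and `Ωn = rn` (with `n = (0,…,k_max)` and
`r = τE[D̃−2] − γ`), the mean, variance and two-time covariance of total
prevalence reduce to linear combinations of `1`, `n`, `n₂` whose
coefficients are elementary integrals of products of exponentials.

Every such integral is assembled from the single primitive

    exp_diff(a, b, t) = (e^{at} − e^{bt}) / (a − b),

evaluated as `t·e^{(a+b)t/2}·sinh(x)/x` with `x = (a−b)t/2`, which is
continuous and fully accurate through every parameter coincidence
(`γ = 0`, `γ = 2τ`, `r = 0`, `r = −2γ`, `2r + 2τ + γ = 0`, `r = −γ`).
One tested limit device replaces eight ad-hoc case branches.

The per-type closed forms require `E[D̃−2] ≠ 0`.  In the fully
degenerate case `r = −γ` (e.g. a 2-regular network) the dominant
eigenvalue is not simple: the mean still evaluates through `exp_diff`,
the Perron type distribution `w₁` is undefined (reported as such), and
the variance functions defer to the quadrature oracle.

`w₁` itself is computed by inverting the factorial moments
`E[(W)_{(i)}] = E[D̃−2]/(E[D̃−2]+i) · E[(D̃−1)_{(i)}]`; it depends only
on the degree distribution, never on `(τ, γ)`.

### Verification oracle

`variance_oracle` integrates the second-moment matrix equation

    V^(k)(t) = ∫₀ᵗ exp(Ωᵀ(t−u)) B_k(u) exp(Ω(t−u)) du

by adaptive quadrature (abs/rel 1e−10/1e−8) directly from the offspring
law's first and second derivatives.  It is deliberately independent of
the closed forms and ships as a public API; the tests require agreement
to a relative 1e−6 on randomized models, and the two-time covariance is
additionally checked against `1ᵀV^(k)(t)M(s−t)1`.

One transcription correction was needed in the established-phase
covariance: projecting the per-type covariance onto `w₁` shows the
τ-block coefficient of the `I₉` integral is `E[(D̃−2)²]`, not
`(E[D̃−2])²`; the two coincide only on regular graphs.  The implemented
form agrees with the independent quadrature oracle.

## Extinction

`π_k(t)` solves the backward system

    dπ_k/dt = −ω_k π_k + γ + τk π_{k−1} Σ_l p̃_{l+1} π_l,  π(0) = 0,

integrated with LSODA at rtol 1e−10 / atol 1e−12 and exposed through a
dense interpolant.  Ultimate probabilities come from monotone fixed-point
iteration from zero (the iteration limit is the minimal fixed point;
damping 0.5 engages only if oscillation is detected, which monotonicity
precludes in practice), with `π_0 = 1` pinned exactly so drift cannot
contaminate the `k ≥ 1` equations.  Certain extinction is returned
directly when `r ≤ 0`.

Around the ODE solution the package provides: the Markov upper bound
`q_k(t) ≤ k·(e^{rt}−e^{−γt})/E[D̃−2] + e^{−γt}`; the linearised
("internal") lower bound on `π_k`; and, for `r < 0`, the matched
asymptotic survival `q_k^{(A)}(t) = (τk e^{rt} + γe^{−ω_k t})/ω_k`,
which is crude but respects both the early (`ω_k`-driven) and late
(`r`-driven) regimes.  Late-time constants (`lim e^{−rt}q_1(t)` for
`−γ < r < 0`) are estimated numerically with an explicit plateau check;
no closed forms exist.

### Conditioning on extinction

A supercritical process conditioned on ultimate extinction is again a
branching process with tilted PGF `P̃_k(s) = P_k(πs)/π_k`.  Its mean
rate matrix, derived directly from the tilted offspring law, is

    Ω̃_{l,k} = (π_{l−1}/π_l) τl (π_k p̃_{k+1} + S δ_{l,k+1}) − ω_l δ_{l,k},
    S = Σ_j p̃_{j+1} π_j,

where the `S` factor arises from marginalising the excess-degree child
when counting the type-`l−1` child.  This matrix is similar (via
`diag(π)`) to the Jacobian of the extinction ODEs at their fixed point —
a property the tests verify — so the survival gap `q_k(t) − (1 − π_k)`
decays at its dominant eigenvalue `r̃ < 0`.  For the 3-regular τ=2, γ=1
example, `r̃ = −γ = −1` and the next eigenvalue (−1.09) is close, so the
numerically observed decay approaches `r̃` slowly; the decay-rate test is
correspondingly loose (5% at late times).  Per-type decay *constants*
are estimated numerically only: the relevant spectral theory assumes an
irreducibility that the type-0 row breaks.

## Established phase and the Gaussian approximation

Conditional on non-extinction the type frequencies converge to `w₁`, so
an epidemic observed from its first passage of prevalence `K` is
modelled as `K` independent single-ancestor processes with type counts
`K·w₁` (largest-remainder apportionment in the moment formulas;
multinomial sampling when simulating).  Sums of independent subtrees
give `E[Z(t)] = Ke^{rt}`, `var(Z(t)) = K·w₁ᵀv(t)`, and the analogous
covariance; by the CLT the prevalence process is approximately Gaussian
for large `K`.  Both the elementary direct forms and the `w₁`
projections are implemented and must agree — a built-in transcription
guard.  These results assume a finite maximal degree; unbounded
distributions must be truncated first (below).

## Truncation of unbounded degree distributions

Ignoring individuals of effective degree above a cutoff `κ` is
equivalent to restricting `D̃` to `{1,…,κ+1}` (renormalised) and
replacing `τ` by `τ·P(D̃ ≤ κ+1)`.  `truncate` returns the original pmf
restricted to degrees `≤ κ+1` and renormalised — size-biasing that pmf
reproduces exactly the restricted `D̃` law, since common rescalings of
`p` cancel — together with the effective rate.  Analytic distributions
(e.g. `poisson`) are materialised with a tail-mass bound (default
1e−10); truncated moments converge monotonically as the cutoff grows,
which the tests check.  Moment convergence needs `E[D³] < ∞`; the
package does not police tail conditions beyond the stated bound.

## Simulation

Both epidemic modes are exact Gillespie simulations with per-individual
aggregated rates (`γ` + `τ` × susceptible-neighbour count, or unpaired
stub count), individual selection by rejection against the maximal
degree, and counter-based substreams (`default_rng([seed, replicate])`)
so every run is reproducible bit-for-bit.

- `full_network` pairs all stubs first and keeps self-loops/multi-edges
  with their multiplicity (parallel edges transmit at `2τ` until the
  target is infected).
- `effective_degree` pairs stubs lazily: a transmission consumes one of
  the infector's stubs and a uniform stub from the global unpaired pool;
  both effective degrees decrement (by 2 on self-pairing), recovered
  individuals' stubs stay in the pool, and a lone leftover stub's
  contact goes nowhere.  Constant-time swap-remove pools make one
  million-node epidemic run in seconds without storing the graph.

The two modes are equal in distribution; the tests compare their
extinction fractions and mean prevalence at matched times.  The restart
protocol shifts time zero to the first passage of a threshold `K`
(replicates that never reach `K` are excluded and counted — the
behaviour for such runs is otherwise unspecified); the single-seed
protocol starts from one uniformly chosen infective, where early
extinction dominates the variance.  `simulate_branching` runs the
approximating process itself and is the Monte Carlo oracle for all
closed forms.

## Inference

For evenly spaced counts `I(0), I(δt), …` the transition density is
Gaussian with mean `I(t)e^{rδt}` and variance given by the
established-phase formula with `K = I(t)` — i.e. the infective types are
re-equilibrated to `w₁` at each observation, an approximation inherited
from the established-phase theory.  The likelihood conditions on the
first observation and multiplies the transitions; series that hit zero
are truncated there with a warning (the Gaussian model is undefined at
extinction).

The surface is a narrow ridge along constant `r = τE[D̃−2] − γ`: `r` is
strongly identified by the mean growth, while the orthogonal direction
is informed only by the variance structure.  The optimiser therefore
works in `(r, log τ)` coordinates (Nelder–Mead with one restart, since
simplices collapse along flat ridges), and the observed information is
computed by central finite differences in `(r, τ)` — where the stiff and
soft directions separate without cancellation — then mapped to `(τ, γ)`
by the delta method.  Confidence intervals are `±1.96` standard errors
with lower bounds clipped at zero.  Auto-initialisation takes `r₀` from
a log-linear regression of the counts and `γ₀ = 1`; fits are
init-independent to 1e−4 in the tests.  Misspecifying the degree
distribution leaves `r̂` essentially unchanged but biases `τ̂` — with a
3-regular assumption on heavier-tailed data, upward.

## Problem sizes and what the tests show

Monte Carlo checks run at sizes chosen to give 4-standard-error
resolution in seconds to minutes: 10⁴ branching replicates for moment
and extinction consistency, 1.5–2×10³ network epidemics (N = 10⁴) for
mode agreement and branching-approximation checks, 100 repeats for CI
coverage, and a single N = 10⁶ epidemic for the end-to-end inference
study.  Synthetic data generators cover exactly the model assumptions —
Markovian dynamics, configuration-model wiring, i.i.d. degrees; passing
tests therefore validate the mathematics and the implementation, not the
adequacy of those assumptions for any real epidemic (real contact
networks have clustering, degree correlation and non-exponential
infectious periods, all out of scope here).  The inference study's
targets are single-realization stochastic quantities whose seed-to-seed
spread matches their reported standard errors.

## Known limitations

- Closed-form variance/covariance (and hence the Gaussian likelihood)
  require `E[D̃−2] ≠ 0` and a finite `k_max` (truncate first).
- Degree-correlated networks, latent periods and non-Markovian
  infectious periods are not modelled.
- The Gaussian transition likelihood degrades for small counts, small
  populations or long observation gaps; no imputation for missing or
  extinct observations is provided.
- Eigenvalue collisions (`r = −γ − iτ` numerically) are reported via a
  warning; Jordan structure is not resolved (the matrix exponential
  remains correct).
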