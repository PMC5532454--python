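# epibranch

Real-time behaviour of Markovian SIR epidemics on configuration-model
networks, analysed through the approximating multitype branching process.

## The problem

Early in an epidemic on a large contact network, the number of infectives
is small and stochastic effects dominate: the epidemic may die out by
chance, and two epidemics with the same parameters can look very
different in real time.  Deterministic ODE models describe proportions in
a large outbreak but say nothing about this early phase.  For a
configuration-model network — a random graph with a prescribed degree
distribution `p_k`, built by pairing half-edges ("stubs") uniformly at
random — the early phase is a multitype Markov branching process in which
an infective's type is its *effective degree* (number of as-yet-unpaired
stubs).  A type-`k` infective dies at rate `ω_k = γ + τk`; with
probability `γ/ω_k` it recovers leaving nothing, otherwise it transmits,
leaving a type-`k−1` copy of itself plus a new infective whose type is
`D̃ − 1`, the size-biased degree of a neighbour minus the edge it was
infected along (`p̃_k = k p_k / E[D]`).

This package implements the closed-form theory of that process and tools
to exploit it:

- **Means** (`bp_core`): the rate matrix
  `Ω_{l,k} = τl(p̃_{k+1} + δ_{l,k+1}) − (γ+τl)δ_{l,k}` with eigenvalues
  `{−γ−iτ : i ≠ 1}` and the growth rate `r = τ E[D̃−2] − γ`; the Perron
  left eigenvector `w₁` (asymptotic type frequencies, a function of the
  degree distribution only); and the exact mean prevalence
  `m(t) = (e^{rt} − e^{−γt}) / E[D̃−2] · n + e^{−γt} 1` per initial type.
- **Variance and covariance** (`bp_moments`): exact elementary closed
  forms `v(t) = α₀1 + α₁n + α₂n₂` and `σ(t,s)`, their `t → ∞` limits,
  and an independent adaptive-quadrature oracle for verification.  Mean
  depends on the first two moments of `D`, variance on the first three.
- **Extinction** (`extinction`): the backward ODE system for `π_k(t)`,
  the ultimate extinction probabilities (minimal PGF fixed point),
  analytic bounds, matched-asymptotic closed forms for subcritical
  epidemics, and the process conditioned on extinction.
- **Established phase** (`established_phase`): an epidemic observed from
  prevalence `K` has types distributed as `w₁`, giving a Gaussian process
  with mean `K e^{rt}` and explicit covariance.
- **Simulation** (`simulator`): exact Gillespie SIR on sampled networks
  or via on-the-fly stub pairing (scales to millions of nodes), plus the
  branching process itself as a Monte Carlo oracle.
- **Inference** (`inference`): Gaussian transition likelihood for evenly
  spaced prevalence counts and maximum-likelihood estimation of `(τ, γ)`
  with asymptotic confidence intervals.

## Worked example

A heterogeneous network with degree masses 1/8, 5/6, 1/24 on degrees
1, 3, 9 (so `E[D] = 3`, `E[D²] = 11`, `E[D³] = 53`), per-edge
transmission rate τ = 2 and recovery rate γ = 1:

```python
import numpy as np
import epibranch as eb

dist = eb.make_distribution([(1, 1/8), (3, 5/6), (9, 1/24)])
model = eb.build_model(dist, tau=2.0, gamma=1.0)

print(f"growth rate r           : {eb.growth_rate(model):.4f}")
print(f"mean prevalence m^(3)(1): {eb.mean_vector(model, 1.0)[3]:.4f}")
print(f"variance v^(3)(1)       : {eb.variance_vector(model, 1.0)[3]:.4f}")
pi = eb.ultimate_extinction(model)
print(f"ultimate extinction pi  : {np.array2string(pi[[1, 3, 9]], precision=4)}")
```

```
growth rate r           : 2.3333
mean prevalence m^(3)(1): 18.2678
variance v^(3)(1)       : 650.6619
ultimate extinction pi  : [0.5702 0.2531 0.0847]
```

`r = 7/3`: prevalence grows like `e^{7t/3}` in epidemics that take off.
An epidemic seeded in a degree-3 individual has mean prevalence 18.3 one
time unit in, with standard deviation `√650.7 ≈ 25.5` — the early phase
is noisy — and goes extinct with probability 0.253.

Fitting rates to one simulated million-node epidemic, observed 40 times
at spacing 0.05 after prevalence first reaches 100:

```python
traj = eb.simulate_sir(dist, 2.0, 1.0, initial=1, seed=[1, 0],
                       mode="effective_degree", n=1_000_000,
                       cap_after=(100, 2.0))
obs = eb.generate_observations(eb.restart_at_threshold(traj, 100), 0.05, 40)
fit = eb.fit_mle(obs, dist)
print(f"tau_hat  : {fit.tau_hat:.3f}  95% CI [{fit.ci95['tau'][0]:.3f}, {fit.ci95['tau'][1]:.3f}]")
print(f"gamma_hat: {fit.gamma_hat:.3f}  95% CI [{fit.ci95['gamma'][0]:.3f}, {fit.ci95['gamma'][1]:.3f}]")
print(f"r_hat    : {fit.r_hat:.3f}")
```

```
tau_hat  : 1.811  95% CI [1.319, 2.303]
gamma_hat: 0.760  95% CI [0.000, 1.581]
r_hat    : 2.258
```

Both rates are recovered (truth τ = 2, γ = 1 inside the intervals); the
growth rate `r` is far more tightly constrained than `τ` or `γ`
individually — the likelihood surface is a ridge along directions of
constant `r`.

A command-line interface mirrors the library:

```sh
epibranch moments    --degrees degrees.txt --tau 2 --gamma 1 --tmax 5 --out moments.csv
epibranch extinction --degrees degrees.txt --tau 2 --gamma 1 --tmax 10 --out pi.csv
epibranch simulate   --degrees degrees.txt --n 10000 --reps 100 --out-dir runs/
epibranch infer      --degrees degrees.txt --obs prevalence.csv --out fit.json
```

Degree files are two whitespace-separated columns `degree probability`
(`#` comments allowed).

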