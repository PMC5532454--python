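"""Exact stochastic simulation: configuration-model SIR and the branching process.

Two equivalent-in-distribution epidemic modes are provided.
``full_network`` pairs all stubs up front and runs a Gillespie simulation
on the realised graph (self-loops and multi-edges are retained: they
become sparse as N grows).  ``effective_degree`` builds the pairing on
the fly: an infective transmits down an unpaired stub, which is paired
with a stub drawn uniformly from the global unpaired pool; both
endpoints' effective degrees decrement (by 2 on a self-pairing), and
recovered individuals' stubs remain in the pool.  The second mode never
stores the graph, so it scales to very large populations.

``simulate_branching`` runs the approximating multitype branching process
directly and serves as the Monte Carlo oracle for every closed-form
moment and extinction result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bp_core import BranchingModel
from .degree_models import DegreeDistribution
from .inference import ObservationSeries, make_series

__all__ = [
    "NetworkRealization",
    "EpidemicTrajectory",
    "SummaryCurves",
    "sample_network",
    "simulate_sir",
    "simulate_branching",
    "restart_at_threshold",
    "monte_carlo_summary",
    "generate_observations",
]

INFECTION, RECOVERY = 0, 1


@dataclass(frozen=True)
class NetworkRealization:
    """A stub-paired configuration-model graph (defects permitted)."""

    N: int
    degrees: np.ndarray = field(repr=False)
    edges: np.ndarray = field(repr=False)  # (E, 2) array of endpoints
    seed: int | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class EpidemicTrajectory:
    """Time-ordered event log with prevalence as a step function."""

    times: np.ndarray = field(repr=False)
    kind: np.ndarray = field(repr=False)      # INFECTION or RECOVERY
    who: np.ndarray = field(repr=False)       # individual id (-1 for branching)
    I: np.ndarray = field(repr=False)         # prevalence after each event
    S: np.ndarray = field(repr=False)
    R: np.ndarray = field(repr=False)
    I0: int
    S0: int
    R0: int
    N: int | None
    t_end: float
    extinct: bool
    origin_shift: float = 0.0

    def prevalence_at(self, t) -> np.ndarray:
        """Step-function prevalence I(t); constant at I0 before the first event."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right")
        vals = np.concatenate([[self.I0], self.I])
        out = vals[idx]
        return out if out.size > 1 else out[0]

    def first_passage(self, K: int) -> int:
        """Index of the first event at which prevalence equals K (-1 if never)."""
        hits = np.nonzero(self.I == K)[0]
        return int(hits[0]) if hits.size else -1


def sample_network(
    dist: DegreeDistribution,
    N: int,
    seed,
    mode: str = "random_degrees",
) -> NetworkRealization:
    """Draw degrees and pair stubs uniformly at random.

    ``random_degrees`` draws i.i.d. degrees from the distribution;
    ``prescribed`` uses a deterministic sequence whose empirical pmf
    matches the distribution as closely as rounding allows (largest
    remainder), shuffled before pairing.  An odd leftover stub is ignored.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    rng = np.random.default_rng(seed)
    if mode == "random_degrees":
        degrees = dist.sample(N, rng).astype(np.int64)
    elif mode == "prescribed":
        raw = N * dist.pmf
        counts = np.floor(raw).astype(int)
        short = N - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
        degrees = np.repeat(np.arange(dist.k_max + 1), counts).astype(np.int64)
        rng.shuffle(degrees)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if degrees.sum() == 0:
        raise ValueError("all degrees are zero")
    stubs = np.repeat(np.arange(N, dtype=np.int64), degrees)
    perm = rng.permutation(stubs)
    if len(perm) % 2:
        perm = perm[:-1]  # odd leftover stub is dropped
    edges = perm.reshape(-1, 2)
    return NetworkRealization(N=N, degrees=degrees, edges=edges, seed=seed)


def _pick_initial(initial, N, rng) -> np.ndarray:
    if isinstance(initial, (int, np.integer)):
        return rng.choice(N, size=int(initial), replace=False)
    return np.asarray(sorted(initial), dtype=np.int64)


def _trajectory(times, kind, who, I, S, R, I0, S0, R0, N, t_end, extinct):
    return EpidemicTrajectory(
        times=np.asarray(times, dtype=float),
        kind=np.asarray(kind, dtype=np.int8),
        who=np.asarray(who, dtype=np.int64),
        I=np.asarray(I, dtype=np.int64),
        S=np.asarray(S, dtype=np.int64),
        R=np.asarray(R, dtype=np.int64),
        I0=I0, S0=S0, R0=R0, N=N, t_end=t_end, extinct=extinct,
    )


def simulate_sir(
    network_or_dist,
    tau: float,
    gamma: float,
    initial,
    seed,
    mode: str = "effective_degree",
    n: int | None = None,
    t_cap: float = np.inf,
    cap_after: tuple[int, float] | None = None,
) -> EpidemicTrajectory:
    """Exact Gillespie SIR simulation.

    ``initial`` is a count (chosen uniformly at random) or an explicit set
    of individuals.  ``cap_after = (K, extra)`` stops the run ``extra``
    time units after prevalence first reaches ``K`` (used by the
    restart-at-threshold protocol to avoid simulating the whole epidemic).
    """
    if tau < 0 or gamma < 0:
        raise ValueError("rates must be non-negative")
    ss = np.random.SeedSequence(seed)
    if mode == "full_network":
        if isinstance(network_or_dist, NetworkRealization):
            return _simulate_full(network_or_dist, tau, gamma, initial, ss,
                                  t_cap, cap_after)
        if n is None:
            raise ValueError("full_network mode with a distribution needs n")
        net_ss, epi_ss = ss.spawn(2)  # independent substreams
        net = sample_network(network_or_dist, n, net_ss)
        return _simulate_full(net, tau, gamma, initial, epi_ss, t_cap, cap_after)
    if mode == "effective_degree":
        if isinstance(network_or_dist, NetworkRealization):
            return _simulate_effective(network_or_dist.degrees, tau, gamma,
                                       initial, ss, t_cap, cap_after)
        if n is None:
            raise ValueError("effective_degree mode with a distribution needs n")
        deg_ss, epi_ss = ss.spawn(2)
        degrees = network_or_dist.sample(
            n, np.random.default_rng(deg_ss)
        ).astype(np.int64)
        return _simulate_effective(degrees, tau, gamma, initial, epi_ss, t_cap,
                                   cap_after)
    raise ValueError(f"unknown mode {mode!r}")


def _simulate_full(net, tau, gamma, initial, seed, t_cap, cap_after):
    rng = np.random.default_rng(seed)
    N = net.N
    # CSR adjacency (multi-edges and self-loops keep their multiplicity)
    src = net.edges.ravel()
    dst = net.edges[:, ::-1].ravel()
    order = np.argsort(src, kind="stable")
    nbr = dst[order]
    counts = np.bincount(src, minlength=N)
    off = np.concatenate([[0], np.cumsum(counts)])

    status = np.zeros(N, dtype=np.int8)  # 0 S, 1 I, 2 R
    init = _pick_initial(initial, N, rng)
    status[init] = 1
    inf_list = np.empty(N, dtype=np.int64)
    inf_pos = np.full(N, -1, dtype=np.int64)
    n_inf = 0
    s_count = np.zeros(N, dtype=np.int64)
    sus_edges = 0
    for i in init:
        inf_list[n_inf] = i
        inf_pos[i] = n_inf
        n_inf += 1
    for i in init:
        c = int(np.sum(status[nbr[off[i]:off[i + 1]]] == 0))
        s_count[i] = c
        sus_edges += c
    dmax = int(counts.max()) if N else 1

    I, S, R = n_inf, N - n_inf, 0
    t = 0.0
    cap = t_cap
    threshold_hit = cap_after is not None and I == cap_after[0]
    if threshold_hit:
        cap = min(cap, cap_after[1])
    times, kinds, whos, Is, Ss, Rs = [], [], [], [], [], []
    I0, S0, R0 = I, S, R

    while n_inf > 0:
        total = gamma * n_inf + tau * sus_edges
        t += rng.exponential() / total
        if t > cap:
            t = cap
            break
        if rng.random() * total < gamma * n_inf:
            idx = int(rng.integers(n_inf))
            i = int(inf_list[idx])
            status[i] = 2
            sus_edges -= int(s_count[i])
            n_inf -= 1
            last = inf_list[n_inf]
            inf_list[idx] = last
            inf_pos[last] = idx
            inf_pos[i] = -1
            I -= 1
            R += 1
            times.append(t); kinds.append(RECOVERY); whos.append(i)
            Is.append(I); Ss.append(S); Rs.append(R)
        else:
            while True:
                idx = int(rng.integers(n_inf))
                i = int(inf_list[idx])
                if rng.random() * dmax < s_count[i]:
                    break
            cand = nbr[off[i]:off[i + 1]]
            sus = cand[status[cand] == 0]
            j = int(sus[rng.integers(len(sus))])
            status[j] = 1
            for u in nbr[off[j]:off[j + 1]]:
                u = int(u)
                if u != j and status[u] == 1:
                    s_count[u] -= 1
                    sus_edges -= 1
            cj = int(np.sum(status[nbr[off[j]:off[j + 1]]] == 0))
            s_count[j] = cj
            sus_edges += cj
            inf_list[n_inf] = j
            inf_pos[j] = n_inf
            n_inf += 1
            I += 1
            S -= 1
            times.append(t); kinds.append(INFECTION); whos.append(j)
            Is.append(I); Ss.append(S); Rs.append(R)
            if cap_after is not None and not threshold_hit and I == cap_after[0]:
                threshold_hit = True
                cap = min(cap, t + cap_after[1])
    extinct = n_inf == 0
    return _trajectory(times, kinds, whos, Is, Ss, Rs, I0, S0, R0, N,
                       t if extinct else min(t, cap), extinct)


def _simulate_effective(degrees, tau, gamma, initial, seed, t_cap, cap_after):
    rng = np.random.default_rng(seed)
    N = len(degrees)
    S_tot = int(degrees.sum())
    if S_tot == 0:
        raise ValueError("all degrees are zero")
    off = np.concatenate([[0], np.cumsum(degrees)]).astype(np.int64)
    owner = np.repeat(np.arange(N, dtype=np.int64), degrees)
    # per-owner segments of unpaired stub ids, compacted in place
    seg = np.arange(S_tot, dtype=np.int64)
    spos = np.arange(S_tot, dtype=np.int64)
    own_count = degrees.copy()
    # global pool of unpaired stubs (swap-remove)
    pool = np.arange(S_tot, dtype=np.int64)
    ppos = np.arange(S_tot, dtype=np.int64)
    n_pool = S_tot

    def pool_remove(s):
        nonlocal n_pool
        p = ppos[s]
        n_pool -= 1
        last = pool[n_pool]
        pool[p] = last
        ppos[last] = p

    def owner_remove(s):
        i = owner[s]
        sl = spos[s]
        last_slot = off[i] + own_count[i] - 1
        other = seg[last_slot]
        seg[sl] = other
        spos[other] = sl
        seg[last_slot] = s
        spos[s] = last_slot
        own_count[i] -= 1

    status = np.zeros(N, dtype=np.int8)
    init = _pick_initial(initial, N, rng)
    status[init] = 1
    inf_list = np.empty(N, dtype=np.int64)
    inf_pos = np.full(N, -1, dtype=np.int64)
    n_inf = 0
    inf_stubs = 0
    for i in init:
        inf_list[n_inf] = i
        inf_pos[i] = n_inf
        n_inf += 1
        inf_stubs += int(own_count[i])
    dmax = int(degrees.max())

    I, S, R = n_inf, N - n_inf, 0
    t = 0.0
    cap = t_cap
    threshold_hit = cap_after is not None and I == cap_after[0]
    if threshold_hit:
        cap = min(cap, cap_after[1])
    times, kinds, whos, Is, Ss, Rs = [], [], [], [], [], []
    I0, S0, R0 = I, S, R

    while n_inf > 0:
        total = gamma * n_inf + tau * inf_stubs
        if total <= 0:
            break
        t += rng.exponential() / total
        if t > cap:
            t = cap
            break
        if rng.random() * total < gamma * n_inf:
            idx = int(rng.integers(n_inf))
            i = int(inf_list[idx])
            status[i] = 2  # unpaired stubs stay in the pool
            inf_stubs -= int(own_count[i])
            n_inf -= 1
            last = inf_list[n_inf]
            inf_list[idx] = last
            inf_pos[last] = idx
            inf_pos[i] = -1
            I -= 1
            R += 1
            times.append(t); kinds.append(RECOVERY); whos.append(i)
            Is.append(I); Ss.append(S); Rs.append(R)
        else:
            while True:
                idx = int(rng.integers(n_inf))
                i = int(inf_list[idx])
                if rng.random() * dmax < own_count[i]:
                    break
            s = int(seg[off[i] + own_count[i] - 1])  # transmitting stub
            owner_remove(s)
            pool_remove(s)
            inf_stubs -= 1
            if n_pool == 0:
                continue  # lone leftover stub: contact goes nowhere
            s2 = int(pool[int(rng.integers(n_pool))])
            j = int(owner[s2])
            pool_remove(s2)
            owner_remove(s2)
            if status[j] == 1:
                inf_stubs -= 1  # includes self-pairing (j == i): decrement by 2 total
            elif status[j] == 0:
                status[j] = 1
                inf_list[n_inf] = j
                inf_pos[j] = n_inf
                n_inf += 1
                inf_stubs += int(own_count[j])
                I += 1
                S -= 1
                times.append(t); kinds.append(INFECTION); whos.append(j)
                Is.append(I); Ss.append(S); Rs.append(R)
                if cap_after is not None and not threshold_hit and I == cap_after[0]:
                    threshold_hit = True
                    cap = min(cap, t + cap_after[1])
    extinct = n_inf == 0
    return _trajectory(times, kinds, whos, Is, Ss, Rs, I0, S0, R0, N,
                       t if extinct else min(t, cap), extinct)


def simulate_branching(
    model: BranchingModel,
    initial,
    seed,
    t_cap: float,
    max_pop: int | None = None,
) -> EpidemicTrajectory:
    """Direct simulation of the multitype branching process.

    ``initial`` is a single type k or an array of per-type counts.  A
    type-j individual dies at rate ``gamma + tau*j``; with probability
    ``gamma/(gamma + tau*j)`` it leaves nothing, otherwise offspring
    ``{j-1, L}`` with ``L ~ D~ - 1``.
    """
    rng = np.random.default_rng(seed)
    km = model.k_max
    z = np.zeros(km + 1, dtype=np.int64)
    if isinstance(initial, (int, np.integer)):
        z[int(initial)] = 1
    else:
        z[:] = np.asarray(initial, dtype=np.int64)
    omega = model.gamma + model.tau * np.arange(km + 1, dtype=float)
    cdf_L = np.cumsum(model.ptilde_shift)
    Z = int(z.sum())
    I0 = Z
    t = 0.0
    times, kinds, whos, Is = [], [], [], []
    while Z > 0:
        rates = z * omega
        total = float(rates.sum())
        t += rng.exponential() / total
        if t > t_cap:
            t = t_cap
            break
        u = rng.random() * total
        j = int(np.searchsorted(np.cumsum(rates), u, side="right"))
        z[j] -= 1
        if rng.random() * omega[j] < model.gamma:
            Z -= 1
            times.append(t); kinds.append(RECOVERY); whos.append(-1); Is.append(Z)
        else:
            z[j - 1] += 1
            L = int(np.searchsorted(cdf_L, rng.random(), side="right"))
            z[L] += 1
            Z += 1
            times.append(t); kinds.append(INFECTION); whos.append(-1); Is.append(Z)
        if max_pop is not None and Z >= max_pop:
            break
    zeros = np.zeros(len(times), dtype=np.int64)
    return _trajectory(times, kinds, whos, Is, zeros, zeros, I0, 0, 0, None,
                       t, Z == 0)


def restart_at_threshold(traj: EpidemicTrajectory, K: int) -> EpidemicTrajectory:
    """Shift the time origin to the first instant prevalence equals K."""
    if traj.I0 == K:
        return traj
    idx = traj.first_passage(K)
    if idx < 0:
        raise ValueError(f"trajectory never reaches prevalence {K}")
    shift = float(traj.times[idx])
    sl = slice(idx + 1, None)
    return EpidemicTrajectory(
        times=traj.times[sl] - shift,
        kind=traj.kind[sl],
        who=traj.who[sl],
        I=traj.I[sl],
        S=traj.S[sl],
        R=traj.R[sl],
        I0=int(traj.I[idx]),
        S0=int(traj.S[idx]),
        R0=int(traj.R[idx]),
        N=traj.N,
        t_end=traj.t_end - shift,
        extinct=traj.extinct,
        origin_shift=shift,
    )


@dataclass(frozen=True)
class SummaryCurves:
    """Monte Carlo summaries across replicates on a common time grid."""

    times: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    extinct_frac: np.ndarray
    se_mean: np.ndarray
    se_var: np.ndarray
    M: int
    n_excluded: int = 0


def _summaries(samples: np.ndarray, times) -> dict:
    M = samples.shape[0]
    mean = samples.mean(axis=0)
    if M > 1:
        var = samples.var(axis=0, ddof=1)
        m4 = ((samples - mean) ** 4).mean(axis=0)
        se_var = np.sqrt(np.maximum(m4 - var ** 2, 0.0) / M)
    else:
        var = np.full(len(times), np.nan)
        se_var = np.full(len(times), np.nan)
    return dict(
        mean=mean,
        var=var,
        extinct_frac=(samples == 0).mean(axis=0),
        se_mean=np.sqrt(var / M) if M > 1 else np.full(len(times), np.nan),
        se_var=se_var,
    )


def monte_carlo_summary(
    dist: DegreeDistribution,
    tau: float,
    gamma: float,
    n: int,
    times,
    M: int,
    seed: int,
    protocol="single",
    mode: str = "effective_degree",
) -> SummaryCurves:
    """Per-grid-point mean, variance and extinction fraction over M replicates.

    ``protocol`` is ``"single"`` (one uniformly chosen initial infective)
    or ``("restart", K)`` (time origin reset at first passage of prevalence
    K; runs that never reach K are excluded and counted).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    times = np.asarray(times, dtype=float)
    horizon = float(times[-1])
    samples = []
    excluded = 0
    for rep in range(M):
        sub = [seed, rep]  # counter-based substream per replicate
        if protocol == "single":
            traj = simulate_sir(dist, tau, gamma, 1, sub, mode=mode, n=n,
                                t_cap=horizon)
            samples.append(traj.prevalence_at(times))
        else:
            kind, K = protocol
            if kind != "restart":
                raise ValueError(f"unknown protocol {protocol!r}")
            traj = simulate_sir(dist, tau, gamma, 1, sub, mode=mode, n=n,
                                cap_after=(K, horizon))
            if traj.first_passage(K) < 0 and traj.I0 != K:
                excluded += 1
                continue
            samples.append(restart_at_threshold(traj, K).prevalence_at(times))
    if not samples:
        raise ValueError("no replicate reached the restart threshold")
    samples = np.asarray(samples, dtype=float)
    return SummaryCurves(times=times, M=len(samples), n_excluded=excluded,
                         **_summaries(samples, times))


def generate_observations(
    traj: EpidemicTrajectory, dt: float, n_obs: int
) -> ObservationSeries:
    """Prevalence at times 0, dt, ..., n_obs*dt (I(0) plus n_obs observations)."""
    t_last = n_obs * dt
    if not traj.extinct and traj.t_end < t_last - 1e-12:
        raise ValueError(
            f"trajectory covers [0, {traj.t_end:g}] but {t_last:g} is required"
        )
    times = np.arange(n_obs + 1) * dt
    counts = np.atleast_1d(traj.prevalence_at(times))
    return make_series(times, counts)
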