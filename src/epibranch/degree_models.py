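"""Degree distributions, size-biased transforms and truncation.

A configuration-model network is specified by the probability mass
function ``p_k`` of the degree ``D`` of a typical individual.  The degree
of a typical *neighbour* is the size-biased variable ``D~`` with mass
``p~_k = k p_k / E[D]``; a newly infected individual has effective degree
``D~ - 1`` because one stub is used up by the infecting edge.  Everything
downstream (growth rate, variance, extinction) is driven by low-order
moments of ``D~``, which are cached here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Tuple

import numpy as np

__all__ = [
    "DegreeDistribution",
    "SizeBiasedMoments",
    "make_distribution",
    "read_degree_file",
    "regular",
    "poisson",
    "size_bias",
    "factorial_moment_tilde",
    "truncate",
]

#: input pmfs may deviate from unit mass by this much before being rejected
INPUT_NORM_TOL = 1e-9
#: internal invariants are enforced to this tolerance
INTERNAL_TOL = 1e-12


@dataclass(frozen=True)
class DegreeDistribution:
    """Probability mass over degrees 0..k_max with cached raw moments."""

    pmf: np.ndarray  # dense over 0..k_max, sums to 1
    k_max: int
    mu: float        # E[D]
    mu2: float       # E[D^2]
    mu3: float       # E[D^3]

    def __post_init__(self):
        object.__setattr__(self, "pmf", np.asarray(self.pmf, dtype=float))

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.k_max + 1)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw i.i.d. degrees."""
        return rng.choice(self.k_max + 1, size=size, p=self.pmf)


@dataclass(frozen=True)
class SizeBiasedMoments:
    """Moments of the size-biased degree ``D~`` (and of ``D~ - 1``, ``D~ - 2``).

    ``factorial`` holds the factorial moments ``mu[i] = E[(D~-1)_(i)]`` for
    i = 0..k_max; they vanish for i >= k_max because ``D~ - 1 <= k_max - 1``.
    """

    pmf_tilde: np.ndarray          # dense over 0..k_max (index = degree), p~_0 = 0
    mu_tilde: float                # E[D~] = E[D^2]/E[D]
    mu_tilde_m1: float             # E[D~ - 1]
    mu_tilde_m2: float             # E[D~ - 2]
    mu_sq_m2: float                # E[(D~ - 2)^2]
    mu_sq_m1_p1: float             # E[(D~ - 1)^2] + 1
    var_tilde: float               # var(D~)
    factorial: np.ndarray = field(repr=False)  # mu^{[i]}_{D~-1}, i = 0..k_max

    @property
    def k_max(self) -> int:
        return len(self.pmf_tilde) - 1


def _finalise(pmf: np.ndarray) -> DegreeDistribution:
    pmf = pmf / pmf.sum()
    k_max = int(np.max(np.nonzero(pmf)[0])) if np.any(pmf > 0) else 0
    pmf = pmf[: k_max + 1]
    k = np.arange(k_max + 1, dtype=float)
    return DegreeDistribution(
        pmf=pmf,
        k_max=k_max,
        mu=float(k @ pmf),
        mu2=float((k ** 2) @ pmf),
        mu3=float((k ** 3) @ pmf),
    )


def make_distribution(pairs: Iterable[Tuple[int, float]]) -> DegreeDistribution:
    """Build a :class:`DegreeDistribution` from ``(degree, probability)`` pairs.

    The mass is renormalised when it deviates from 1 by less than
    ``1e-9``; larger deviations are rejected as user error.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty degree distribution")
    seen = set()
    for k, p in pairs:
        if int(k) != k or k < 0:
            raise ValueError(f"degree {k!r} is not a non-negative integer")
        if p < 0:
            raise ValueError(f"negative probability {p!r} for degree {k}")
        if k in seen:
            raise ValueError(f"duplicate degree {k}")
        seen.add(k)
    total = sum(p for _, p in pairs)
    if abs(total - 1.0) >= INPUT_NORM_TOL:
        raise ValueError(f"probabilities sum to {total!r}, not 1 (tolerance 1e-9)")
    k_max = max(int(k) for k, _ in pairs)
    pmf = np.zeros(k_max + 1)
    for k, p in pairs:
        pmf[int(k)] = p
    return _finalise(pmf)


def read_degree_file(path: str | Path) -> DegreeDistribution:
    """Read a two-column ``degree probability`` text file ('#' comments allowed)."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"expected two columns, got {line!r}")
        pairs.append((int(fields[0]), float(fields[1])))
    return make_distribution(pairs)


def regular(k: int) -> DegreeDistribution:
    """Point mass at degree ``k`` (a k-regular network)."""
    return make_distribution([(k, 1.0)])


def poisson(mean: float, tail_mass: float = 1e-10) -> DegreeDistribution:
    """Poisson degree distribution truncated to leave at most ``tail_mass`` above k_max.

    Unbounded analytic distributions are supported only through explicit
    truncation; moments of the truncated size-biased degree converge to
    those of the full distribution as the tail bound shrinks.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    k_max = 1
    while True:
        # complement of the cdf at k_max
        tail = 1.0 - math.fsum(
            math.exp(-mean) * mean ** j / math.factorial(j) for j in range(k_max + 1)
        )
        if tail <= tail_mass:
            break
        k_max += 1
    pmf = np.array(
        [math.exp(-mean) * mean ** j / math.factorial(j) for j in range(k_max + 1)]
    )
    return _finalise(pmf)


def size_bias(dist: DegreeDistribution) -> SizeBiasedMoments:
    """Size-biased transform ``p~_k = k p_k / E[D]`` and its cached moments."""
    if dist.mu <= 0:
        raise ValueError("size-biasing requires E[D] > 0")
    k = dist.support.astype(float)
    pt = k * dist.pmf / dist.mu
    mu_t = dist.mu2 / dist.mu
    mu_sq = dist.mu3 / dist.mu  # E[D~^2]
    i = np.arange(dist.k_max + 1)
    # falling factorials (k-1)_(i) = (k-1)(k-2)...(k-i), clamped to 0 once a
    # factor goes negative (degrees are integers, so the product is then 0)
    fall = np.ones((dist.k_max + 1, dist.k_max + 1))
    for j in range(1, dist.k_max + 1):
        fall[:, j] = fall[:, j - 1] * (k - j)
        fall[k - j < 0, j] = 0.0
    factorial = fall.T @ pt
    factorial[i >= dist.k_max] = 0.0
    return SizeBiasedMoments(
        pmf_tilde=pt,
        mu_tilde=mu_t,
        mu_tilde_m1=mu_t - 1.0,
        mu_tilde_m2=mu_t - 2.0,
        mu_sq_m2=mu_sq - 4.0 * mu_t + 4.0,
        mu_sq_m1_p1=mu_sq - 2.0 * mu_t + 2.0,
        var_tilde=mu_sq - mu_t ** 2,
        factorial=factorial,
    )


def factorial_moment_tilde(sb: SizeBiasedMoments, i: int) -> float:
    """i-th factorial moment of ``D~ - 1``; zero for ``i >= k_max``."""
    if i < 0:
        raise ValueError("order must be non-negative")
    if i >= sb.k_max:
        return 0.0
    return float(sb.factorial[i])


def truncate(
    dist: DegreeDistribution, k_max_new: int, tau: float
) -> Tuple[DegreeDistribution, float]:
    """Truncate an (effectively unbounded) distribution at type ``k_max_new``.

    Individuals of effective degree above ``k_max_new`` are ignored, which
    amounts to restricting the size-biased degree to ``{1, ..., k_max_new+1}``
    (renormalised) and replacing the per-edge rate ``tau`` by
    ``tau * P(D~ <= k_max_new + 1)``.  A no-op when the support already fits.
    """
    if k_max_new < 1:
        raise ValueError("k_max_new must be >= 1")
    if k_max_new >= dist.k_max:
        return dist, tau
    sb = size_bias(dist)
    keep = dist.pmf[: k_max_new + 2]
    if not np.any(keep[1:] > 0):
        raise ValueError("no mass on positive degrees below the cutoff")
    effective_tau = tau * float(sb.pmf_tilde[: k_max_new + 2].sum())
    return _finalise(keep.copy()), effective_tau
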