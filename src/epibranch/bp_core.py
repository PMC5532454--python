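"""Mean structure of the multitype branching process.

During the early phase of an SIR epidemic on a configuration-model
network, the infectives form a multitype Markov branching process in
which an individual's type is its *effective degree* (number of unpaired
stubs).  A type-k individual dies at rate ``omega_k = gamma + tau*k``;
with probability ``gamma/omega_k`` it leaves no offspring, otherwise it
leaves two: one of type ``k - 1`` and one of type ``D~ - 1``.

This module builds the mean rate matrix

    Omega[l, k] = tau*l*(p~_{k+1} + delta_{l,k+1}) - (gamma + tau*l)*delta_{l,k},

whose dominant eigenvalue ``r = tau*E[D~ - 2] - gamma`` is the Malthusian
growth rate, together with the Perron left eigenvector ``w1`` (asymptotic
type frequencies among infectives) and the closed-form mean prevalence

    m(t) = (e^{rt} - e^{-gamma t}) / E[D~ - 2] * n + e^{-gamma t} * 1,

where ``n = (0, 1, ..., k_max)`` indexes the initial type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb, factorial

import numpy as np
import scipy.linalg

from .degree_models import DegreeDistribution, SizeBiasedMoments, size_bias
from .numerics import exp_diff

__all__ = [
    "BranchingModel",
    "MeanCurve",
    "build_model",
    "growth_rate",
    "spectrum",
    "perron_left_vector",
    "mean_matrix",
    "mean_vector",
    "mean_curve",
]


@dataclass(frozen=True)
class BranchingModel:
    """A degree distribution together with epidemic rates and derived structure."""

    dist: DegreeDistribution
    sb: SizeBiasedMoments
    tau: float
    gamma: float
    omega: np.ndarray = field(repr=False)  # (k_max+1) x (k_max+1) rate matrix
    r: float                               # dominant eigenvalue of omega
    w1: np.ndarray = field(repr=False)     # Perron left eigenvector, sums to 1

    @property
    def k_max(self) -> int:
        return self.dist.k_max

    @property
    def n(self) -> np.ndarray:
        """Type indices (0, 1, ..., k_max)."""
        return np.arange(self.k_max + 1, dtype=float)

    @property
    def n2(self) -> np.ndarray:
        return self.n ** 2

    @property
    def ptilde_shift(self) -> np.ndarray:
        """Entry ``l`` is ``p~_{l+1}``, the offspring-type pmf of ``D~ - 1``."""
        pt = self.sb.pmf_tilde
        out = np.zeros(self.k_max + 1)
        out[: self.k_max] = pt[1:]
        return out


@dataclass(frozen=True)
class MeanCurve:
    """Mean prevalence ``m^(k)(t)`` per initial type on a time grid."""

    times: np.ndarray
    m: np.ndarray  # shape (len(times), k_max+1)


def build_model(dist: DegreeDistribution, tau: float, gamma: float) -> BranchingModel:
    if tau < 0 or gamma < 0:
        raise ValueError("rates must be non-negative")
    if tau == 0 and gamma == 0:
        raise ValueError("tau and gamma cannot both be zero")
    sb = size_bias(dist)
    km = dist.k_max
    l = np.arange(km + 1, dtype=float)
    pt_shift = np.zeros(km + 1)
    pt_shift[:km] = sb.pmf_tilde[1:]
    omega = tau * l[:, None] * pt_shift[None, :]
    omega[np.arange(1, km + 1), np.arange(km)] += tau * l[1:]
    omega[np.diag_indices(km + 1)] -= gamma + tau * l
    r = tau * sb.mu_tilde_m2 - gamma
    model = BranchingModel(
        dist=dist, sb=sb, tau=tau, gamma=gamma, omega=omega, r=r, w1=None
    )
    try:
        object.__setattr__(model, "w1", _w1_from_factorial_moments(sb))
    except ValueError:
        # degenerate E[D~-2+i] = 0: the dominant eigenvalue is not simple and
        # no asymptotic type distribution exists; means remain well defined
        pass
    _warn_on_eigenvalue_collision(model)
    return model


def _w1_from_factorial_moments(sb: SizeBiasedMoments) -> np.ndarray:
    """Perron left eigenvector from the factorial-moment inversion formula.

    The i-th factorial moment of the w1 distribution is
    ``E[D~-2] / (E[D~-2] + i) * mu^{[i]}_{D~-1}``; inverting the factorial
    moments gives the mass function directly.  Invariant to (tau, gamma).
    """
    km = sb.k_max
    mu = sb.mu_tilde_m2
    denom = mu + np.arange(km)
    if np.any(np.abs(denom) < 1e-14):
        raise ValueError(
            "degenerate model: E[D~ - 2 + i] = 0 for some i; "
            "the Perron eigenvector is not defined by the inversion formula"
        )
    w = np.zeros(km + 1)
    for k in range(km):
        w[k] = sum(
            (-1) ** (i - k) * comb(i, k) * mu * sb.factorial[i] / (factorial(i) * denom[i])
            for i in range(k, km)
        )
    total = w.sum()
    if total <= 0:
        raise ValueError("inversion formula produced a non-positive mass function")
    return w / total


def _warn_on_eigenvalue_collision(model: BranchingModel, tol: float = 1e-10) -> None:
    lam = spectrum(model)
    lam = np.sort(lam)
    if np.any(np.diff(lam) < tol):
        warnings.warn(
            "eigenvalue collision: Omega may be non-diagonalisable; "
            "matrix-exponential results remain valid",
            stacklevel=3,
        )


def growth_rate(model: BranchingModel) -> float:
    """Malthusian growth rate ``r = tau*E[D~ - 2] - gamma``."""
    return model.r


def spectrum(model: BranchingModel) -> np.ndarray:
    """All eigenvalues of Omega, sorted descending.

    They are ``-gamma - i*tau`` for i in {0, 2, 3, ..., k_max} plus the
    dominant eigenvalue ``r``.
    """
    i = np.array([j for j in range(model.k_max + 1) if j != 1], dtype=float)
    lam = np.concatenate([[-model.gamma - model.tau * j for j in i], [model.r]])
    return np.sort(lam)[::-1]


def perron_left_vector(model: BranchingModel) -> np.ndarray:
    """Asymptotic type-frequency distribution ``w1`` (left eigenvector for r)."""
    if model.w1 is None:
        raise ValueError(
            "degenerate model: E[D~ - 2 + i] = 0 for some i, so the "
            "inversion formula does not define a Perron eigenvector"
        )
    return model.w1


def mean_matrix(model: BranchingModel, t: float) -> np.ndarray:
    """``M(t) = expm(Omega t)``; entry (k, i) is ``E[Z_i(t)]`` from one type-k."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return scipy.linalg.expm(model.omega * t)


def mean_vector(model: BranchingModel, t: float) -> np.ndarray:
    """Closed-form mean prevalence per initial type.

    ``(e^{rt} - e^{-gamma t}) / E[D~-2] = tau * exp_diff(r, -gamma, t)``
    since ``r + gamma = tau*E[D~-2]``, which also covers the degenerate
    branch ``r = -gamma`` continuously.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    return model.tau * exp_diff(model.r, -model.gamma, t) * model.n + np.exp(
        -model.gamma * t
    ) * np.ones(model.k_max + 1)


def mean_curve(model: BranchingModel, times: np.ndarray) -> MeanCurve:
    times = np.asarray(times, dtype=float)
    return MeanCurve(times=times, m=np.array([mean_vector(model, t) for t in times]))
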