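"""Moments of an epidemic observed from prevalence K in its established phase.

Conditional on non-extinction, the relative type frequencies of
infectives converge to the Perron eigenvector ``w1``.  An epidemic
observed from the first time prevalence reaches ``K`` (large) is
therefore modelled as ``K`` independent single-ancestor branching
processes whose types are distributed as ``w1``; sums of the
single-ancestor moments give

    E[Z(t)]        = K e^{rt}
    var(Z(t))      = K w1' v(t)          (closed form below)
    cov(Z(t),Z(s)) = K w1' sigma(t, s)

and, for large K, the central limit theorem makes the prevalence process
approximately Gaussian with these moments.  The variance/covariance are
implemented both directly (elementary-integral form) and as w1
projections of the per-type formulas; the two routes must agree, which
serves as a built-in transcription guard.
"""

from __future__ import annotations

import numpy as np

from .bp_core import BranchingModel, mean_vector
from .bp_moments import (
    _integrals_cov,
    _integrals_var,
    covariance_vector,
    variance_vector,
)
from .extinction import ExtinctionSolution
from .numerics import exp_diff

__all__ = [
    "conditional_moments",
    "established_mean",
    "established_variance",
    "established_variance_projection",
    "established_covariance",
    "established_covariance_projection",
    "seed_types",
]


def conditional_moments(
    model: BranchingModel, solution: ExtinctionSolution, k: int, t: float
):
    """Mean and variance of prevalence from one type-k, given survival to t."""
    q = float(solution.q_at(t)[k])
    if q < 1e-12:
        raise ValueError("survival probability vanishes; conditioning undefined")
    m = float(mean_vector(model, t)[k])
    v = float(variance_vector(model, t)[k])
    mean = m / q
    variance = v / q - (1.0 - q) * mean ** 2
    return mean, variance


def established_mean(model: BranchingModel, K: int, t) -> float:
    """``K e^{rt}`` — the w1-projection of the mean curve is exactly e^{rt}."""
    return K * np.exp(model.r * np.asarray(t, dtype=float))


def _i9(model: BranchingModel, t):
    # e^{rt}(e^{rt}-1)/r with the r -> 0 limit handled
    return exp_diff(2.0 * model.r, model.r, t)


def established_variance(model: BranchingModel, K: int, t) -> float:
    """Variance of prevalence started from K w1-distributed infectives."""
    sb = model.sb
    mu = sb.mu_tilde_m2
    g, tau = model.gamma, model.tau
    i4 = _integrals_var(model, t)[3]
    i9 = _i9(model, t)
    s2 = sb.var_tilde
    return K * (
        g * (i9 + (s2 + 2.0) / (sb.mu_tilde * mu) * i4)
        + tau / mu * (mu ** 2 * i9 + s2 * i4)
    )


def established_variance_projection(model: BranchingModel, K: int, t: float) -> float:
    """Same quantity via ``K w1' v(t)`` (independent transcription check)."""
    return K * float(model.w1 @ variance_vector(model, t))


def established_covariance(model: BranchingModel, K: int, t, s) -> float:
    """Covariance ``cov(Z(t), Z(s))`` of established-phase prevalence, t <= s."""
    if np.any(np.asarray(t) > np.asarray(s)):
        raise ValueError("requires t <= s")
    sb = model.sb
    mu = sb.mu_tilde_m2
    g, tau = model.gamma, model.tau
    i6 = _integrals_cov(model, t)[0]
    i9 = _i9(model, t)
    s2 = sb.var_tilde
    lag = tau * exp_diff(model.r, -model.gamma, np.asarray(s) - np.asarray(t))
    # the tau block carries E[(D~-2)^2] = mu^2 + s2 (projection of the per-type
    # covariance; confirmed against the quadrature oracle)
    brace = g / sb.mu_tilde * (sb.mu_sq_m1_p1 * i9 - (s2 + 2.0) * i6) + tau * (
        sb.mu_sq_m2 * i9 - s2 * i6
    )
    # lag = (e^{r(s-t)} - e^{-gamma(s-t)}) / mu, via tau*exp_diff since r+gamma = tau*mu
    return np.exp(-g * (np.asarray(s) - np.asarray(t))) * established_variance(
        model, K, t
    ) + K * lag * brace


def established_covariance_projection(
    model: BranchingModel, K: int, t: float, s: float
) -> float:
    """Same quantity via ``K w1' sigma(t, s)``."""
    return K * float(model.w1 @ covariance_vector(model, t, s))


def seed_types(
    model: BranchingModel,
    K: int,
    rng: np.random.Generator | None = None,
    method: str = "multinomial",
) -> np.ndarray:
    """Type counts for K established-phase seeds distributed as w1.

    ``multinomial`` samples (for simulation); ``apportion`` rounds
    ``K w1`` deterministically by largest remainder (for moment formulas).
    """
    if method == "multinomial":
        if rng is None:
            raise ValueError("multinomial seeding needs an rng")
        return rng.multinomial(K, model.w1)
    if method == "apportion":
        raw = K * model.w1
        counts = np.floor(raw).astype(int)
        short = K - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
        return counts
    raise ValueError(f"unknown method {method!r}")
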