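"""Extinction probabilities over time and the process conditioned on extinction.

The extinction probability ``pi_k(t)`` of a process started from one
type-k individual satisfies the backward system

    d pi_k / dt = -(gamma + tau k) pi_k + gamma
                  + tau k pi_{k-1} sum_l p~_{l+1} pi_l,      pi_k(0) = 0,

which is solved numerically (no closed form exists).  The ultimate
probabilities ``pi_k = pi_k(inf)`` form the minimal fixed point of the
offspring PGF and are found by monotone fixed-point iteration from zero.
Analytic devices around the ODE solution: a survival upper bound from
the mean, a matched-asymptotic closed form in the subcritical regime,
numerical late-time decay constants, and the subcritical process obtained
by conditioning a supercritical process on ultimate extinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.integrate
import scipy.linalg

from .bp_core import BranchingModel
from .numerics import exp_diff

__all__ = [
    "ExtinctionSolution",
    "ConditionedModel",
    "LateTimeConstant",
    "solve_extinction",
    "ultimate_extinction",
    "survival_upper_bound",
    "matched_asymptotics",
    "late_time_constant",
    "conditioned_model",
    "conditional_mean",
]


@dataclass(frozen=True)
class ExtinctionSolution:
    """Extinction probabilities on a grid, with a dense interpolant."""

    times: np.ndarray
    pi: np.ndarray = field(repr=False)  # (len(times), k_max+1)
    pi_ultimate: np.ndarray
    _dense: object = field(repr=False, default=None)

    @property
    def q(self) -> np.ndarray:
        """Survival probabilities ``1 - pi``."""
        return 1.0 - self.pi

    def pi_at(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("t must be non-negative")
        return np.clip(self._dense(t), 0.0, 1.0)

    def q_at(self, t: float) -> np.ndarray:
        return 1.0 - self.pi_at(t)


def _rhs_factory(model: BranchingModel):
    g, tau = model.gamma, model.tau
    k = np.arange(model.k_max + 1, dtype=float)
    pt_shift = model.ptilde_shift

    def rhs(_t, pi):
        s = pt_shift @ pi
        shifted = np.empty_like(pi)
        shifted[0] = 0.0
        shifted[1:] = pi[:-1]
        return -(g + tau * k) * pi + g + tau * k * shifted * s

    return rhs


def solve_extinction(model: BranchingModel, t_grid) -> ExtinctionSolution:
    """Integrate the extinction ODEs from ``pi(0) = 0`` on an increasing grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must increase from 0")
    sol = scipy.integrate.solve_ivp(
        _rhs_factory(model),
        (0.0, float(t_grid[-1])),
        np.zeros(model.k_max + 1),
        method="LSODA",
        t_eval=t_grid,
        rtol=1e-10,
        atol=1e-12,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"extinction ODE solver failed: {sol.message}")
    pi = np.clip(sol.y.T, 0.0, 1.0)
    return ExtinctionSolution(
        times=t_grid,
        pi=pi,
        pi_ultimate=ultimate_extinction(model),
        _dense=sol.sol,
    )


def ultimate_extinction(model: BranchingModel, tol: float = 1e-12,
                        max_iter: int = 100_000) -> np.ndarray:
    """Minimal non-negative fixed point of the offspring PGF.

    ``pi_0 = 1`` exactly (a type-0 individual never reproduces); for the
    (sub)critical case ``r <= 0`` extinction is certain and all ones are
    returned.  The iteration from the zero vector increases monotonically
    to the minimal fixed point, so no damping is required; damping 0.5 is
    applied only if oscillation is ever detected.
    """
    km = model.k_max
    if model.r <= 0:
        return np.ones(km + 1)
    g, tau = model.gamma, model.tau
    k = np.arange(km + 1, dtype=float)
    pt_shift = model.ptilde_shift
    pi = np.zeros(km + 1)
    prev_delta = None
    for _ in range(max_iter):
        s = pt_shift @ pi
        shifted = np.concatenate([[0.0], pi[:-1]])
        new = (g + tau * k * shifted * s) / (g + tau * k)
        new[0] = 1.0
        delta = new - pi
        if prev_delta is not None and np.any(delta * prev_delta < -tol):
            new = 0.5 * (new + pi)  # damp on oscillation
            delta = new - pi
        if np.max(np.abs(delta)) < tol:
            return new
        prev_delta = delta
        pi = new
    raise RuntimeError("ultimate extinction iteration did not converge")


def survival_upper_bound(model: BranchingModel, k: int, t: float) -> float:
    """Markov bound ``q_k(t) <= E[Z^(k)(t)]`` in closed form."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return float(
        k * model.tau * exp_diff(model.r, -model.gamma, t) + np.exp(-model.gamma * t)
    )


def matched_asymptotics(model: BranchingModel, k: int, t):
    """Internal, external and matched closed-form survival approximations.

    Valid in the subcritical regime ``r < 0``: the internal solution drops
    the quadratic terms of the extinction ODEs (exact as t -> 0, an upper
    bound for q), the external solution is the late-time exponential decay,
    and the matched solution glues them through the shared intermediate
    limit ``tau k / omega_k``.
    """
    if model.r >= 0:
        raise ValueError("matched asymptotics requires a subcritical model (r < 0)")
    t = np.asarray(t, dtype=float)
    wk = model.gamma + model.tau * k
    internal = (model.tau * k + model.gamma * np.exp(-wk * t)) / wk
    external = model.tau * k / wk * np.exp(model.r * t)
    matched = (model.tau * k * np.exp(model.r * t) + model.gamma * np.exp(-wk * t)) / wk
    return internal, external, matched


class LateTimeConstant(NamedTuple):
    value: float
    converged: bool


def late_time_constant(model: BranchingModel, solution: ExtinctionSolution) -> LateTimeConstant:
    """Estimate ``c = lim e^{-rt} q_1(t)`` from an ODE solution.

    Requires ``-gamma < r < 0``; then ``q_k(t) ~ c k e^{rt}`` for k >= 1.
    ``converged`` is False when the scaled survival has not plateaued
    (relative spread above 1e-4 over the last tenth of the grid).
    """
    if not (-model.gamma < model.r < 0):
        raise ValueError("late-time constant defined for -gamma < r < 0")
    t = solution.times
    scaled = np.exp(-model.r * t) * solution.q[:, 1]
    tail = scaled[t >= 0.9 * t[-1]]
    spread = (tail.max() - tail.min()) / max(tail.mean(), 1e-300)
    return LateTimeConstant(value=float(scaled[-1]), converged=bool(spread < 1e-4))


@dataclass(frozen=True)
class ConditionedModel:
    """Supercritical process conditioned on ultimate extinction (subcritical)."""

    omega_tilde: np.ndarray = field(repr=False)
    r_tilde: float
    pi_ultimate: np.ndarray


def conditioned_model(model: BranchingModel) -> ConditionedModel:
    """Tilted rate matrix of the process conditioned on extinction.

    The tilted PGF is ``P~_k(s) = P_k(pi s) / pi_k``, whose mean matrix is

        Omega~[l, k] = (pi_{l-1} / pi_l) tau l (pi_k p~_{k+1} + S delta_{l,k+1})
                       - (gamma + tau l) delta_{l,k},

    with ``S = sum_j p~_{j+1} pi_j`` (marginalising the excess-degree child
    when counting the type l-1 child).  Omega~ is similar to the Jacobian of
    the extinction ODEs at their fixed point, so the gap
    ``q_k(t) - (1 - pi_k)`` decays at rate r~, the dominant eigenvalue.
    For r > 0 the conditioned process is subcritical (r~ < 0); a
    (sub)critical model has trivial tilt and ``Omega~ = Omega``.
    """
    pi = ultimate_extinction(model)
    if np.any(pi <= 0):
        raise ValueError("cannot condition: some ultimate extinction probability is 0")
    km = model.k_max
    l = np.arange(km + 1, dtype=float)
    pt_shift = model.ptilde_shift
    s_star = float(pt_shift @ pi)
    shifted = np.concatenate([[1.0], pi[:-1]])  # pi_{l-1}, unused for l = 0
    omega_tilde = (
        model.tau * l * shifted / pi
    )[:, None] * (pi * pt_shift)[None, :]
    omega_tilde[np.arange(1, km + 1), np.arange(km)] += (
        model.tau * l[1:] * shifted[1:] / pi[1:] * s_star
    )
    omega_tilde[np.diag_indices(km + 1)] -= model.gamma + model.tau * l
    r_tilde = float(np.max(np.linalg.eigvals(omega_tilde).real))
    return ConditionedModel(omega_tilde=omega_tilde, r_tilde=r_tilde, pi_ultimate=pi)


def conditional_mean(cm: ConditionedModel, k: int, t: float) -> float:
    """Mean population size at t of the conditioned process from one type-k."""
    return float(scipy.linalg.expm(cm.omega_tilde * t)[k, :].sum())
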