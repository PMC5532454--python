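"""Closed-form variance and covariance of prevalence, with a quadrature oracle.

The variance of total prevalence started from one type-k individual has
the exact form ``v(t) = alpha0(t) 1 + alpha1(t) n + alpha2(t) n2`` where
the alpha coefficients are linear combinations of five elementary
integrals I1..I5; the two-time covariance has the analogous form with
integrals I6..I8.  Every integral is a sum of divided exponential
differences, so all the "denominator is zero" parameter coincidences
(gamma = 0, gamma = 2*tau, r = 0, r = -2*gamma, 2r + 2*tau + gamma = 0)
are handled by the single :func:`exp_diff` primitive.

The quadrature oracle integrates the second-moment matrix equation

    V^(k)(t) = int_0^t expm(Omega^T (t-u)) B_k(u) expm(Omega (t-u)) du

directly and is the independent cross-check for the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.integrate
import scipy.linalg

from .bp_core import BranchingModel
from .numerics import exp_diff

__all__ = [
    "exp_diff",
    "VarianceCurve",
    "CovarianceSurface",
    "variance_vector",
    "variance_curve",
    "variance_oracle",
    "covariance_vector",
    "asymptotic_variance_limit",
    "asymptotic_cv2",
]


def _require_nondegenerate(model: BranchingModel) -> float:
    mu = model.sb.mu_tilde_m2
    if abs(mu) < 1e-12:
        raise ValueError(
            "closed-form variance requires E[D~ - 2] != 0; "
            "use variance_oracle for this degenerate model"
        )
    return mu


def _integrals_var(model: BranchingModel, t):
    r, g, tau = model.r, model.gamma, model.tau
    i1 = exp_diff(r, -2.0 * g, t)
    i2 = exp_diff(-g, -2.0 * g, t)
    i3 = exp_diff(r, r - g, t) - i1
    i4 = exp_diff(2.0 * r, r, t) - 2.0 * i3 - i1
    i5 = (
        exp_diff(2.0 * r, -(g + 2.0 * tau), t)
        - 2.0 * exp_diff(r - g, -(g + 2.0 * tau), t)
        + exp_diff(-(g + 2.0 * tau), -2.0 * g, t)
    )
    return i1, i2, i3, i4, i5


def _alphas(model: BranchingModel, t):
    mu = _require_nondegenerate(model)
    sb = model.sb
    r, g, tau = model.r, model.gamma, model.tau
    i1, i2, i3, i4, i5 = _integrals_var(model, t)
    alpha0 = g * i2
    alpha1 = g / mu * (
        i1 - i2 + 2.0 * i3 + sb.mu_sq_m1_p1 / (mu * sb.mu_tilde) * (i4 - i5)
    ) + tau * (i1 + 2.0 * i3 + sb.mu_sq_m2 / mu ** 2 * i4)
    alpha2 = g / mu ** 2 * i5
    return alpha0, alpha1, alpha2


def variance_vector(model: BranchingModel, t: float) -> np.ndarray:
    """Exact variance of total prevalence per initial type 0..k_max."""
    if t < 0:
        raise ValueError("t must be non-negative")
    a0, a1, a2 = _alphas(model, t)
    return a0 * np.ones(model.k_max + 1) + a1 * model.n + a2 * model.n2


@dataclass(frozen=True)
class VarianceCurve:
    times: np.ndarray
    alpha0: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    v: np.ndarray = field(repr=False)  # (len(times), k_max+1)


def variance_curve(model: BranchingModel, times) -> VarianceCurve:
    times = np.asarray(times, dtype=float)
    a0, a1, a2 = _alphas(model, times)
    v = (
        a0[:, None] * np.ones(model.k_max + 1)
        + a1[:, None] * model.n
        + a2[:, None] * model.n2
    )
    return VarianceCurve(times=times, alpha0=a0, alpha1=a1, alpha2=a2, v=v)


def _offspring_structure(model: BranchingModel):
    """Per-type mean vectors f_k and fluctuation matrices C_k of the offspring law."""
    km = model.k_max
    tau, g = model.tau, model.gamma
    pt = model.ptilde_shift  # pt[i] = p~_{i+1}
    fs, cs = [], []
    for k in range(km + 1):
        wk = g + tau * k
        f = tau * k / wk * pt.copy()
        if k >= 1:
            f[k - 1] += tau * k / wk
        d2 = np.zeros((km + 1, km + 1))
        if k >= 1:
            d2[:, k - 1] += tau * k / wk * pt
            d2[k - 1, :] += tau * k / wk * pt
        uk = np.zeros(km + 1)
        uk[k] = 1.0
        c = wk * (
            d2 + np.diag(f) - np.outer(uk, f) - np.outer(f, uk) + np.outer(uk, uk)
        )
        fs.append(f)
        cs.append(c)
    return fs, cs


def variance_oracle(
    model: BranchingModel, k: int, t: float, rtol: float = 1e-8, atol: float = 1e-10
) -> np.ndarray:
    """Full type-covariance matrix ``V^(k)(t)`` by adaptive quadrature.

    Ships as a public verification API: the closed forms are exact, the
    oracle is independent of them.
    """
    if not 0 <= k <= model.k_max:
        raise ValueError("k out of range")
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0:
        return np.zeros((model.k_max + 1, model.k_max + 1))
    _, cs = _offspring_structure(model)
    omega = model.omega

    def integrand(u):
        row = scipy.linalg.expm(omega * u)[k, :]
        b = sum(row[l] * cs[l] for l in range(model.k_max + 1))
        e = scipy.linalg.expm(omega * (t - u))
        return e.T @ b @ e

    res, err = scipy.integrate.quad_vec(integrand, 0.0, t, epsabs=atol, epsrel=rtol)
    return res


def _integrals_cov(model: BranchingModel, t):
    r, g, tau = model.r, model.gamma, model.tau
    i6 = exp_diff(r, r - g, t)
    i7 = exp_diff(2.0 * r, r, t) - i6
    i8 = exp_diff(2.0 * r, -(g + 2.0 * tau), t) - exp_diff(r - g, -(g + 2.0 * tau), t)
    return i6, i7, i8


def _betas(model: BranchingModel, t):
    mu = _require_nondegenerate(model)
    sb = model.sb
    g, tau = model.gamma, model.tau
    i6, i7, i8 = _integrals_cov(model, t)
    beta1 = g / mu * (sb.mu_sq_m1_p1 / sb.mu_tilde * (i7 - i8) + mu * i6) + tau / mu * (
        sb.mu_sq_m2 * i7 + mu ** 2 * i6
    )
    beta2 = g / mu * i8
    return beta1, beta2


def covariance_vector(model: BranchingModel, t: float, s: float) -> np.ndarray:
    """Exact covariance ``cov(Z(t), Z(s))`` per initial type, for ``t <= s``."""
    if t > s:
        raise ValueError("requires t <= s")
    if t < 0:
        raise ValueError("t must be non-negative")
    b1, b2 = _betas(model, t)
    lag = model.tau * exp_diff(model.r, -model.gamma, s - t)
    return lag * (b1 * model.n + b2 * model.n2) + np.exp(
        -model.gamma * (s - t)
    ) * variance_vector(model, t)


@dataclass(frozen=True)
class CovarianceSurface:
    """Callable two-time covariance of prevalence per initial type."""

    model: BranchingModel

    def beta1(self, t: float) -> float:
        return _betas(self.model, t)[0]

    def beta2(self, t: float) -> float:
        return _betas(self.model, t)[1]

    def sigma(self, t: float, s: float, k: int) -> float:
        t, s = min(t, s), max(t, s)
        return float(covariance_vector(self.model, t, s)[k])


def asymptotic_variance_limit(model: BranchingModel) -> np.ndarray:
    """``lim_{t->inf} e^{-2rt} v(t)`` per initial type (supercritical only)."""
    if model.r <= 0:
        raise ValueError("asymptotic variance limit requires r > 0")
    mu = _require_nondegenerate(model)
    sb = model.sb
    tau, g, r = model.tau, model.gamma, model.r
    denom = 2.0 * sb.mu_tilde_m1 * tau - g  # equals 2r + 2*tau + gamma
    if denom <= 0:
        raise ValueError("scaled variance diverges: 2*E[D~-1]*tau - gamma <= 0")
    coef_n = 2.0 * tau * sb.mu_tilde_m1 * (sb.mu_sq_m2 * tau + g) / r
    return (coef_n * model.n + g * model.n2) / (mu ** 2 * denom)


def asymptotic_cv2(model: BranchingModel, k: int) -> float:
    """Limiting squared coefficient of variation of prevalence from one type-k."""
    if k < 1:
        raise ValueError("requires k >= 1 (type 0 has vanishing mean growth)")
    sb = model.sb
    tau, g, r = model.tau, model.gamma, model.r
    denom = 2.0 * sb.mu_tilde_m1 * tau - g
    if r <= 0 or denom <= 0:
        raise ValueError("limit defined only for supercritical, non-divergent models")
    return (g + 2.0 * tau * sb.mu_tilde_m1 * (sb.mu_sq_m2 * tau + g) / (k * r)) / denom
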