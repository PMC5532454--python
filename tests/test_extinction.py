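import numpy as np
import pytest

import epibranch as eb
from epibranch.extinction import conditional_mean, late_time_constant


@pytest.fixture(scope="module")
def sol_reg3(model_reg3):
    return eb.solve_extinction(model_reg3, np.linspace(0.0, 15.0, 301))


class TestSolveExtinction:
    def test_type_zero_is_pure_death(self, sol_reg3):
        t = sol_reg3.times
        assert np.allclose(sol_reg3.pi[:, 0], 1.0 - np.exp(-t), atol=1e-8)

    def test_monotone_and_bounded(self, sol_reg3, model_reg3):
        assert np.all(np.diff(sol_reg3.pi, axis=0) >= -1e-9)
        assert np.all(sol_reg3.pi >= 0) and np.all(sol_reg3.pi <= 1)
        assert np.all(sol_reg3.pi <= sol_reg3.pi_ultimate + 1e-6)

    def test_converges_to_ultimate(self, sol_reg3):
        assert sol_reg3.pi_at(15.0)[2] == pytest.approx(3 / 8, abs=1e-4)

    def test_no_transmission_all_types_identical(self, reg3):
        m = eb.build_model(reg3, 0.0, 1.0)
        sol = eb.solve_extinction(m, np.linspace(0.0, 3.0, 31))
        for k in range(4):
            assert np.allclose(sol.pi[:, k], 1.0 - np.exp(-sol.times), atol=1e-8)

    def test_grid_must_start_at_zero(self, model_reg3):
        with pytest.raises(ValueError):
            eb.solve_extinction(model_reg3, np.linspace(1.0, 2.0, 5))

    def test_monte_carlo_agreement(self, model_reg3, sol_reg3):
        """Extinct fraction of simulated processes within 4 binomial SE."""
        M = 10_000
        checkpoints = np.array([0.5, 1.0, 2.0])
        extinct = np.zeros((M, len(checkpoints)))
        for rep in range(M):
            tr = eb.simulate_branching(model_reg3, 3, [303, rep], t_cap=2.0)
            extinct[rep] = tr.prevalence_at(checkpoints) == 0
        for j, t in enumerate(checkpoints):
            p = sol_reg3.pi_at(t)[3]
            se = np.sqrt(p * (1 - p) / M)
            assert abs(extinct[:, j].mean() - p) < 4 * se


class TestUltimateExtinction:
    def test_subcritical_certain(self, reg3):
        m = eb.build_model(reg3, 0.4, 1.0)  # r < 0
        assert np.all(eb.ultimate_extinction(m) == 1.0)

    def test_regular_exact_values(self, model_reg3):
        # minimal root of 8x^2 - 11x + 3 and back-substitution
        assert np.allclose(
            eb.ultimate_extinction(model_reg3), [1.0, 7 / 12, 3 / 8, 59 / 224],
            atol=1e-10,
        )

    def test_nonincreasing_in_type(self):
        rng = np.random.default_rng(3)
        from conftest import random_model

        for _ in range(10):
            m = random_model(rng, supercritical=True)
            pi = eb.ultimate_extinction(m)
            assert np.all(np.diff(pi[1:]) <= 1e-10)

    def test_monte_carlo_agreement(self, model_reg3):
        M = 20_000
        extinct = sum(
            eb.simulate_branching(model_reg3, 3, [404, rep], t_cap=15.0, max_pop=200).extinct
            for rep in range(M)
        )
        p = 59 / 224
        se = np.sqrt(p * (1 - p) / M)
        assert abs(extinct / M - p) < 4 * se


class TestBoundsAndAsymptotics:
    def test_upper_bound_tight_for_type_zero(self, model_reg3, sol_reg3):
        for t in (0.3, 1.0, 2.0):
            assert eb.survival_upper_bound(model_reg3, 0, t) == pytest.approx(
                np.exp(-t), rel=1e-12
            )
            assert sol_reg3.q_at(t)[0] == pytest.approx(np.exp(-t), abs=1e-8)

    def test_bounds_sandwich_ode_solution(self, reg3):
        """Mean bound above, linearised solution below, for random subcritical models."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            tau, gamma = rng.uniform(0.1, 0.9), 1.0
            m = eb.build_model(reg3, tau, gamma)
            if m.r >= 0:
                continue
            grid = np.linspace(0.0, 10.0, 101)
            sol = eb.solve_extinction(m, grid)
            for k in range(1, 4):
                upper = np.array([eb.survival_upper_bound(m, k, t) for t in grid])
                internal = eb.matched_asymptotics(m, k, grid)[0]
                assert np.all(sol.q[:, k] <= np.minimum(upper, 1.0) + 1e-8)
                assert np.all(sol.q[:, k] <= internal + 1e-8)

    def test_matched_solution_starts_at_one(self, reg3):
        m = eb.build_model(reg3, 0.3, 1.0)
        for k in range(4):
            assert eb.matched_asymptotics(m, k, 0.0)[2] == pytest.approx(1.0)

    def test_type_zero_all_approximations_exact(self, reg3):
        m = eb.build_model(reg3, 0.3, 1.0)
        t = np.linspace(0, 5, 21)
        internal, _, matched = eb.matched_asymptotics(m, 0, t)
        assert np.allclose(internal, np.exp(-t))
        assert np.allclose(matched, np.exp(-t))

    def test_matched_beats_pieces_in_their_bad_regimes(self, reg3):
        """The glued approximation outperforms the internal piece late and the
        external piece early (crude but uniformly sane closed form)."""
        m = eb.build_model(reg3, 0.5, 1.0)  # r = -1/2
        grid = np.linspace(0.0, 12.0, 241)
        sol = eb.solve_extinction(m, grid)
        k = 2
        internal, external, matched = eb.matched_asymptotics(m, k, grid)
        q = sol.q[:, k]
        late = grid > 8.0
        early = grid < 0.5
        assert np.max(np.abs(matched - q)[late]) < np.max(np.abs(internal - q)[late])
        assert np.max(np.abs(matched - q)[early]) < np.max(np.abs(external - q)[early])

    def test_supercritical_refused(self, model_reg3):
        with pytest.raises(ValueError):
            eb.matched_asymptotics(model_reg3, 1, 1.0)


class TestLateTimeBehaviour:
    def test_survival_ratio_approaches_type(self, reg3):
        """q_k(t) / q_1(t) -> k in the moderately subcritical regime."""
        m = eb.build_model(reg3, 0.5, 1.0)  # -gamma < r = -1/2 < 0
        horizon = 10.0 / abs(m.r)
        sol = eb.solve_extinction(m, np.linspace(0.0, horizon, 801))
        q = sol.q_at(horizon)
        for k in (2, 3):
            assert q[k] / q[1] == pytest.approx(k, rel=2e-2)

    def test_constant_estimate_converges_and_positive(self, reg3):
        m = eb.build_model(reg3, 0.5, 1.0)
        sol = eb.solve_extinction(m, np.linspace(0.0, 20.0, 801))
        c = late_time_constant(m, sol)
        assert c.converged and c.value > 0

    def test_strongly_subcritical_decay_is_recovery_driven(self):
        """For r < -gamma, e^{gamma t} q_k(t) -> 1 - k / E[D~-2], free of tau."""
        dist = eb.make_distribution([(1, 0.9), (2, 0.1)])
        m = eb.build_model(dist, 1.0, 1.0)  # r = -9/11*1 - 1 < -gamma
        assert m.r < -m.gamma
        sol = eb.solve_extinction(m, np.linspace(0.0, 15.0, 301))
        q = sol.q_at(15.0)
        mu = m.sb.mu_tilde_m2  # negative here
        for k in range(m.k_max + 1):
            assert np.exp(m.gamma * 15.0) * q[k] == pytest.approx(
                1.0 - k / mu, rel=2e-2
            )

    def test_rate_not_constant_requires_window(self, model_reg3):
        with pytest.raises(ValueError):
            late_time_constant(
                model_reg3, eb.solve_extinction(model_reg3, np.linspace(0, 1, 11))
            )


class TestConditionedProcess:
    def test_subcritical_tilt_is_identity(self, reg3):
        m = eb.build_model(reg3, 0.4, 1.0)
        cm = eb.conditioned_model(m)
        assert np.allclose(cm.omega_tilde, m.omega)

    def test_supercritical_conditioned_is_subcritical(self, model_reg3, model_d3):
        for m in (model_reg3, model_d3):
            assert eb.conditioned_model(m).r_tilde < 0

    def test_conditional_mean_starts_at_one(self, model_reg3):
        cm = eb.conditioned_model(model_reg3)
        for k in range(4):
            assert conditional_mean(cm, k, 0.0) == pytest.approx(1.0)

    def test_survival_decays_at_tilted_rate(self, model_reg3):
        """q_k(t) - (1 - pi_k) ~ const * e^{r~ t}: 5% on the late log-slope
        (loose: a near-degenerate eigenvalue pair makes convergence slow)."""
        cm = eb.conditioned_model(model_reg3)
        sol = eb.solve_extinction(model_reg3, np.linspace(0.0, 25.0, 501))
        pi_inf = cm.pi_ultimate
        t1, t2 = 18.0, 24.0
        for k in (1, 2):
            y1 = sol.q_at(t1)[k] - (1.0 - pi_inf[k])
            y2 = sol.q_at(t2)[k] - (1.0 - pi_inf[k])
            slope = np.log(y2 / y1) / (t2 - t1)
            assert slope == pytest.approx(cm.r_tilde, rel=5e-2)

    def test_tilted_matrix_is_similar_to_ode_jacobian(self, model_d3):
        """Omega~ conjugated by diag(pi) equals the Jacobian of the extinction
        ODE system at its fixed point (independent construction)."""
        cm = eb.conditioned_model(model_d3)
        pi = cm.pi_ultimate
        km, tau, g = model_d3.k_max, model_d3.tau, model_d3.gamma
        pt = model_d3.ptilde_shift
        s_star = pt @ pi
        jac = np.zeros((km + 1, km + 1))
        for k in range(km + 1):
            sh = pi[k - 1] if k >= 1 else 0.0
            for l in range(km + 1):
                jac[k, l] += tau * k * ((l == k - 1) * s_star + sh * pt[l])
            jac[k, k] -= g + tau * k
        D = np.diag(pi)
        assert np.allclose(np.linalg.inv(D) @ jac @ D, cm.omega_tilde, atol=1e-12)
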