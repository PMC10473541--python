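import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.stats import kstest

from grnattract import (AttractorResult, NetworkArchitecture, PerturbationSpec,
                        SystemState, attractor_distance, find_attractors_global,
                        integrate_rk4, match_endpoint, ode_rhs, perturb_state)
from grnattract.benchmark import default_kinetics
from grnattract.profiles import ExpressionProfileSet


def unregulated(n, f0=0.5):
    params = default_kinetics(n).with_estimates(f0=np.full(n, f0))
    anet = NetworkArchitecture(np.zeros((n, n), dtype=np.int8))
    return anet, params


class TestOdeRhs:
    def test_unregulated_fixed_point_closed_form(self):
        """At R = (V_min + (V_max−V_min)·f0)/D_mRNA the mRNA derivative
        vanishes for a gene with no regulators."""
        anet, params = unregulated(1, f0=0.5)
        r_star = (params.v_min + (params.v_max - params.v_min) * 0.5) / params.d_mrna
        p_star = params.v_trl * r_star / params.d_protein
        dr, dp = ode_rhs(SystemState(r_star, p_star), anet, params)
        assert np.allclose(dr, 0) and np.allclose(dp, 0)

    def test_knockout_clamp_zeroes_mrna_derivative(self):
        anet, params = unregulated(2)
        state = SystemState([3.0, 3.0], [10.0, 10.0])
        clamp = PerturbationSpec(knockouts=("G0",))
        dr, dp = ode_rhs(state, anet, params, clamp)
        assert dr[0] == 0.0
        assert dr[1] != 0.0
        # protein of the knocked-out gene still decays from the clamped mRNA
        assert dp[0] == pytest.approx(params.v_trl[0] * 0.0
                                      - params.d_protein[0] * 10.0)

    def test_two_gene_activation_hand_arithmetic(self):
        """A→B independent activation: the derivative chain evaluated by
        hand through occupancy, combinatorial term and regulation."""
        params = default_kinetics(2).with_estimates(f0=np.array([0.3, 0.2]),
                                                    k=np.array([2.0, 3.0]))
        anet = NetworkArchitecture([[0, 0], [1, 0]])  # gene B (row 1) <- A
        r = np.array([4.0, 1.0])
        p = np.array([500.0, 30.0])
        t_a = params.t_half_occ[0]
        s = p[0]**3 / (p[0]**3 + t_a**3)          # occupancy with B's k = 3
        f_b = 0.2 + (1 - 0.2) * s                  # C_A = s, C_R = 1
        expected_db = (params.v_min[1]
                       + (params.v_max[1] - params.v_min[1]) * f_b
                       - params.d_mrna[1] * r[1])
        expected_da = (params.v_min[0]
                       + (params.v_max[0] - params.v_min[0]) * 0.3
                       - params.d_mrna[0] * r[0])
        dr, _ = ode_rhs(SystemState(r, p), anet, params)
        assert dr[1] == pytest.approx(expected_db, rel=1e-12)
        assert dr[0] == pytest.approx(expected_da, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        anet, params = unregulated(2)
        with pytest.raises(ValueError, match="dimension"):
            ode_rhs(SystemState([1.0], [1.0]), anet, params)


class TestIntegration:
    def test_unregulated_converges_to_closed_form(self):
        anet, params = unregulated(1, f0=0.5)
        res = integrate_rk4(anet, params, SystemState([0.0], [0.0]), dt=30)
        assert res.converged and not res.oscillatory
        expected = (params.v_min[0] + (params.v_max[0] - params.v_min[0]) * 0.5) \
            / params.d_mrna[0]
        assert res.final_state.r[0] == pytest.approx(expected, rel=1e-4)

    def test_pure_decay_fourth_order_convergence(self):
        """With V_max = V_min ≈ 0 the mRNA decays as R0·exp(−D·t); halving
        the step shrinks the max error by ~16x (classical RK4 order)."""
        n = 1
        params = default_kinetics(n).with_estimates(f0=np.full(n, 0.0))
        params.v_max = np.full(n, 1e-12)
        params.v_min = np.zeros(n)
        anet = NetworkArchitecture(np.zeros((n, n), dtype=np.int8))
        r0, horizon = 100.0, 2000.0

        def max_err(dt):
            res = integrate_rk4(anet, params, SystemState([r0], [0.0]), dt=dt,
                                t_max=horizon, tol=0.0)  # never converge early
            exact = r0 * np.exp(-params.d_mrna[0] * res.steps_taken * dt)
            return abs(res.final_state.r[0] - exact)

        e1, e2 = max_err(200.0), max_err(100.0)
        assert e1 / e2 == pytest.approx(16, rel=0.4)

    def test_linear_system_matches_matrix_exponential(self):
        """The unregulated (linear) 2-gene system endpoint agrees with the
        exact solution via the matrix exponential."""
        anet, params = unregulated(2, f0=0.25)
        r0 = np.array([10.0, 1.0])
        p0 = np.array([100.0, 5000.0])
        dt, steps = 50.0, 40
        res = integrate_rk4(anet, params, SystemState(r0, p0), dt=dt,
                            t_max=dt * (steps + 0.5), tol=0.0)
        # x' = A x + b with x = (R, P)
        n = 2
        A = np.zeros((2 * n, 2 * n))
        A[:n, :n] = -np.diag(params.d_mrna)
        A[n:, :n] = np.diag(params.v_trl)
        A[n:, n:] = -np.diag(params.d_protein)
        b = np.concatenate([params.v_min + (params.v_max - params.v_min) * 0.25,
                            np.zeros(n)])
        x0 = np.concatenate([r0, p0])
        t = res.steps_taken * dt
        x_star = -np.linalg.solve(A, b)
        exact = x_star + expm(A * t) @ (x0 - x_star)
        assert np.allclose(res.final_state.r, exact[:n], rtol=1e-6)
        assert np.allclose(res.final_state.p, exact[n:], rtol=1e-6)

    def test_repression_ring_is_oscillatory(self):
        """A 3-gene repression ring with steep Hill curves sustains bounded
        oscillations; an independent adaptive solver confirms the endpoint
        keeps moving over a long horizon."""
        n = 3
        am = np.zeros((n, n), dtype=np.int8)
        am[0, 2] = am[1, 0] = am[2, 1] = -1
        anet = NetworkArchitecture(am)
        params = default_kinetics(n).with_estimates(f0=np.full(n, 0.9),
                                                    k=np.full(n, 8.0))
        start = SystemState(np.array([15.0, 1.0, 5.0]),
                            np.array([9000.0, 600.0, 3000.0]))
        res = integrate_rk4(anet, params, start, dt=100)
        assert res.oscillatory and not res.converged and not res.diverged

        def rhs(_t, y):
            dr, dp = ode_rhs(SystemState(y[:n], y[n:]), anet, params)
            return np.concatenate([dr, dp])

        y0 = np.concatenate([start.r, start.p])
        sol = solve_ivp(rhs, (0, 3e5), y0, rtol=1e-8, atol=1e-8,
                        dense_output=True)
        late = sol.sol(np.linspace(2.5e5, 3e5, 200))[:n]
        assert late.max() < 100  # bounded
        assert late.std(axis=1).max() > 0.5  # still moving: not a fixed point

    def test_converged_endpoint_has_small_residual(self, small_reference):
        anet, params = small_reference
        res = integrate_rk4(anet, params,
                            SystemState(np.full(3, 5.0), np.full(3, 500.0)),
                            dt=50)
        assert res.converged
        dr, _ = ode_rhs(res.final_state, anet, params)
        norm = params.v_max / params.d_mrna
        assert np.max(np.abs(dr) / norm) < 1e-5


class TestTrajectory:
    def test_recorded_trajectory_matches_endpoint_integration(self):
        """The recorded trajectory's last row equals the endpoint reached by
        the batch integrator with the same step, and pure decay follows the
        exponential closed form along the way."""
        from grnattract import simulate_trajectory
        n = 1
        params = default_kinetics(n).with_estimates(f0=np.full(n, 0.0))
        params.v_max = np.full(n, 1e-12)
        params.v_min = np.zeros(n)
        anet = NetworkArchitecture(np.zeros((n, n), dtype=np.int8))
        times, r, p = simulate_trajectory(anet, params,
                                          SystemState([50.0], [0.0]),
                                          dt=50.0, n_steps=20)
        assert times.shape == (21,) and r.shape == (21, 1)
        exact = 50.0 * np.exp(-params.d_mrna[0] * times)
        # per-step RK4 truncation ~(D*dt)^5/120 accumulates along the horizon
        assert np.allclose(r[:, 0], exact, rtol=1e-4)

    def test_trajectory_respects_clamp(self, small_reference):
        from grnattract import simulate_trajectory
        anet, params = small_reference
        times, r, p = simulate_trajectory(
            anet, params, SystemState(np.full(3, 5.0), np.full(3, 100.0)),
            dt=50.0, n_steps=10, clamps=PerturbationSpec(knockouts=("G1",)))
        assert (r[:, 1] == 0.0).all()


class TestPerturbState:
    def _params(self, n=3):
        return default_kinetics(n).with_estimates(f0=np.full(n, 0.5))

    def test_zero_power_is_identity(self):
        params = self._params()
        prof = np.array([1.0, 5.0, 10.0])
        st = perturb_state(prof, 0.0, np.array([10.0, 10.0, 10.0]),
                           np.random.default_rng(0), params)
        assert np.array_equal(st.r, prof)
        assert np.allclose(st.p, params.v_trl * prof / params.d_protein)

    def test_bounded_by_power_times_maximum(self):
        params = self._params(1)
        rng = np.random.default_rng(1)
        for _ in range(200):
            st = perturb_state(np.array([50.0]), 0.1, np.array([100.0]),
                               rng, params)
            assert 40.0 <= st.r[0] <= 60.0

    def test_perturbation_distribution_is_uniform(self):
        """(R − I)/max over many draws is U(−0.1, 0.1) (KS test, α=0.01)."""
        params = self._params(1)
        rng = np.random.default_rng(2)
        draws = np.array([perturb_state(np.array([50.0]), 0.1,
                                        np.array([100.0]), rng, params).r[0]
                          for _ in range(10_000)])
        rel = (draws - 50.0) / 100.0
        stat = kstest(rel, "uniform", args=(-0.1, 0.2))
        assert stat.pvalue > 0.01

    def test_clipped_at_zero(self):
        params = self._params(1)
        rng = np.random.default_rng(3)
        draws = [perturb_state(np.array([0.5]), 0.5, np.array([100.0]),
                               rng, params).r[0] for _ in range(200)]
        assert min(draws) >= 0.0

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            perturb_state(np.array([1.0]), -0.1, np.array([1.0]),
                          np.random.default_rng(0), self._params(1))


class TestAttractorDistance:
    @pytest.mark.parametrize("a,b,maxima,expected", [
        ([1.0, 2.0], [1.0, 2.0], [1.0, 2.0], 0.0),
        ([1.0, 0.0], [0.0, 1.0], [1.0, 1.0], 1.0),
        ([0.8, 0.4], [1.0, 0.5], [1.0, 1.0], 0.15),
    ])
    def test_values(self, a, b, maxima, expected):
        assert attractor_distance(a, b, maxima) == pytest.approx(expected)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(2, 6)
            maxima = rng.uniform(0.5, 5.0, n)
            x, y, z = (rng.uniform(0, 5, n) for _ in range(3))
            dxy = attractor_distance(x, y, maxima)
            dyx = attractor_distance(y, x, maxima)
            assert dxy >= 0
            assert dxy == pytest.approx(dyx)
            assert attractor_distance(x, x, maxima) == 0
            assert dxy <= attractor_distance(x, z, maxima) + \
                attractor_distance(z, y, maxima) + 1e-12

    def test_zero_maximum_rejected(self):
        with pytest.raises(ValueError):
            attractor_distance([1.0], [1.0], [0.0])


class TestMatchEndpoint:
    def _profiles(self):
        return ExpressionProfileSet(np.array([[1.0, 0.0], [0.0, 1.0]]),
                                    ["A", "B"], ["c0", "c1"])

    def _result(self, r):
        return AttractorResult(SystemState(np.asarray(r), np.zeros(2)),
                               converged=True, oscillatory=False)

    def test_origin_profile_comparison(self):
        idx, d, ok = match_endpoint(self._result([1.0, 0.0]), self._profiles(),
                                    origin_index=0)
        assert (idx, d, ok) == (0, 0.0, True)

    def test_cutoff_semantics(self):
        """distance 0.159 matches at cutoff 0.16; 0.161 does not."""
        profiles = self._profiles()
        for target_d, expect in [(0.159, True), (0.161, False)]:
            endpoint = np.array([1.0 - 2 * target_d, 0.0])
            _, d, ok = match_endpoint(self._result(endpoint), profiles,
                                      origin_index=0, cutoff=0.16)
            assert d == pytest.approx(target_d)
            assert ok is expect

    def test_nearest_profile_with_tie_break(self):
        """Equidistant endpoints deterministically match the lower index."""
        idx, d, _ = match_endpoint(self._result([0.5, 0.5]), self._profiles())
        assert idx == 0
        assert d == pytest.approx(0.5)

    def test_empty_profile_set_rejected(self):
        with pytest.raises((ValueError, IndexError)):
            match_endpoint(self._result([1.0, 0.0]),
                           ExpressionProfileSet(np.ones((2, 1))),
                           origin_index=5)


class TestGlobalAttractorSearch:
    def test_unregulated_system_has_single_attractor(self):
        anet, params = unregulated(2, f0=0.4)
        for levels in (2, 4):
            att, info = find_attractors_global(anet, params, levels=levels)
            assert att.shape[0] == 1
            assert info["n_oscillatory"] == 0

    def test_bistable_self_activator_matches_nullcline_oracle(self, bistable_gene):
        """The 1-D sweep of the steady-state mRNA derivative (with protein
        slaved to its steady state) counts the stable fixed points
        independently of the integrator."""
        anet, params = bistable_gene
        att, _ = find_attractors_global(anet, params, levels=5)

        r = np.linspace(1e-3, params.v_max[0] / params.d_mrna[0], 4000)
        p = params.v_trl[0] * r / params.d_protein[0]
        s = p**params.k[0] / (p**params.k[0] + params.t_half_occ[0]**params.k[0])
        f = params.f0[0] + (1 - params.f0[0]) * s
        dr = params.v_min[0] + (params.v_max[0] - params.v_min[0]) * f \
            - params.d_mrna[0] * r
        signs = np.sign(dr)
        crossings = np.flatnonzero(np.diff(signs) != 0)
        stable = [c for c in crossings if signs[c] > 0 > signs[c + 1]]
        assert att.shape[0] == len(stable) == 2

    def test_returned_attractors_satisfy_residual_contract(self, small_reference):
        anet, params = small_reference
        att, info = find_attractors_global(anet, params, levels=3)
        assert att.shape[0] >= 3
        assert (info["residuals"] < 1e-4).all()

    def test_invariant_under_grid_refinement(self, bistable_gene):
        anet, params = bistable_gene
        att3, _ = find_attractors_global(anet, params, levels=3)
        att5, _ = find_attractors_global(anet, params, levels=5)
        maxima = params.v_max / params.d_mrna
        assert att3.shape == att5.shape
        for a in att3:
            assert min(attractor_distance(a, b, maxima) for b in att5) < 0.01

    def test_grid_cap_refused_explicitly(self):
        anet, params = unregulated(5, f0=0.5)
        with pytest.raises(ValueError, match="cap"):
            find_attractors_global(anet, params, levels=9, cap=1000)

    def test_clamped_gene_fixed_in_grid(self):
        anet, params = unregulated(2, f0=0.4)
        att, _ = find_attractors_global(
            anet, params, levels=3, clamps=PerturbationSpec(knockouts=("G0",)))
        assert att.shape[0] == 1
        assert att[0, 0] == 0.0
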