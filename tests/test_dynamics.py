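"""Discretization, boundary handling, and integration to steady state."""

import numpy as np
import pytest
from scipy.integrate import solve_bvp

import ecostrat as es
from ecostrat.dynamics import (IntegrationSettings, NegativityError,
                               NumericalBlowupError, _rhs_fields)
from ecostrat.model import total_consumption


def make_env(M, gamma=1.0, rho=1.0, K_value=1.0):
    return es.EnvironmentParams.with_defaults(M, gamma=gamma, rho=rho,
                                              K_value=K_value)


class TestInitialState:
    def test_quadratic_resource_profile(self):
        c = es.sample_community(2, 2, 0.0, seed=0)
        env = make_env(2)
        grid = es.Grid1D(256, 100.0)
        s = es.initial_state(c, env, grid)
        # R(x) = K (L-x)^2 / (2L): value 50 at the source, 0 at the far end,
        # inward slope matching the supply flux
        assert np.allclose(s.R[:, 0], 50.0)
        assert np.allclose(s.R[:, -1], 0.0)
        slope0 = (s.R[:, 1] - s.R[:, 0]) / grid.dx
        assert np.allclose(slope0, -1.0, atol=grid.dx / 100)
        x = grid.x
        assert np.allclose(s.R, (100.0 - x) ** 2 / 200.0)

    def test_species_start_homogeneous(self):
        c = es.sample_community(3, 3, 1.0, seed=1)
        s = es.initial_state(c, make_env(3), es.Grid1D(64, 100.0), n0=0.25)
        assert np.all(s.N == 0.25)

    def test_zero_supply_means_zero_resources(self):
        c = es.sample_community(2, 2, 0.0, seed=0)
        s = es.initial_state(c, make_env(2, K_value=0.0), es.Grid1D(64, 100.0))
        assert np.all(s.R == 0)

    def test_rejects_nonpositive_n0(self):
        c = es.sample_community(2, 2, 0.0, seed=0)
        with pytest.raises(ValueError):
            es.initial_state(c, make_env(2), es.Grid1D(64, 100.0), n0=0.0)


class TestSpatialRhs:
    def test_supply_only_acts_at_source_boundary(self):
        # no consumption, no growth, empty resources: only the K flux acts
        c = es.Community(Y=np.ones(2), k=np.zeros((2, 2)),
                         A=np.zeros((2, 2)), m=np.full(2, 0.1))
        env = make_env(2, gamma=0.0, rho=0.0)
        grid = es.Grid1D(64, 100.0)
        state = es.SystemState(N=np.full((2, 64), 0.3), R=np.zeros((2, 64)))
        dN, dR = es.spatial_rhs(state, c, env, grid)
        assert np.all(dN == 0)
        assert np.all(dR[:, 0] > 0)
        assert np.all(dR[:, 1:] == 0)

    def test_uniform_species_have_no_diffusive_part(self):
        c = es.sample_community(3, 3, 0.0, seed=2)
        env = make_env(3, gamma=1.0, rho=0.0)
        grid = es.Grid1D(64, 100.0)
        rng = np.random.default_rng(0)
        N = np.tile(rng.uniform(0.1, 1.0, 3)[:, None], (1, 64))
        R = np.tile(rng.uniform(0.1, 1.0, 3)[:, None], (1, 64))
        state = es.SystemState(N=N, R=R)
        dN, _ = es.spatial_rhs(state, c, env, grid)
        dN_react, _ = es.reaction_terms((N[:, 0], R[:, 0]), c, env)
        assert np.allclose(dN, dN_react[:, None])

    @pytest.mark.parametrize("seed", range(6))
    def test_discrete_mass_balance_identity(self, seed):
        """d/dt of trapezoid resource mass == boundary supply - consumption.

        Checked against direct quadrature of the discretized tendencies at
        randomized states: the ghost-node construction makes the identity
        exact (to rounding), not merely O(dx^2).
        """
        rng = np.random.default_rng(seed)
        S = M = int(rng.integers(1, 5))
        c = es.sample_community(S, M, 1.0, seed=seed)
        env = make_env(M, gamma=rng.uniform(0, 2))
        grid = es.Grid1D(int(rng.integers(32, 200)), 100.0)
        N = rng.uniform(0, 2, (S, grid.n_nodes))
        R = rng.uniform(0, 2, (M, grid.n_nodes))
        _, dR = es.spatial_rhs(es.SystemState(N=N, R=R), c, env, grid)
        dmass = np.trapezoid(dR, dx=grid.dx, axis=1)
        C = total_consumption(N, R, c)
        supply = env.D_R * (env.K - C[:, 0])
        consumption = np.trapezoid(C, dx=grid.dx, axis=1)
        assert np.allclose(dmass, supply - consumption, rtol=1e-10,
                           atol=1e-10)

    def test_label_permutation_symmetry(self):
        rng = np.random.default_rng(3)
        c = es.sample_community(4, 4, 1.0, seed=3)
        env = make_env(4)
        grid = es.Grid1D(48, 100.0)
        N = rng.uniform(0, 2, (4, 48))
        R = rng.uniform(0, 2, (4, 48))
        dN, dR = es.spatial_rhs(es.SystemState(N=N, R=R), c, env, grid)
        p = np.array([2, 0, 3, 1])
        cp = es.Community(Y=c.Y[p], k=c.k[p][:, p], A=c.A[p][:, p], m=c.m[p])
        dNp, dRp = es.spatial_rhs(es.SystemState(N=N[p], R=R[p]), cp, env,
                                  grid)
        assert np.allclose(dNp, dN[p], rtol=1e-12, atol=1e-12)
        assert np.allclose(dRp, dR[p], rtol=1e-12, atol=1e-12)

    def test_literal_right_boundary_injects_resource(self):
        c = es.sample_community(2, 2, 0.0, seed=0)
        env = make_env(2, gamma=0.0, rho=0.0)
        grid = es.Grid1D(64, 100.0)
        N = np.full((2, 64), 0.5)
        R = np.full((2, 64), 1.0)
        state = es.SystemState(N=N, R=R)
        _, dR_closed = es.spatial_rhs(state, c, env, grid)
        _, dR_lit = es.spatial_rhs(state, c, env, grid,
                                   right_boundary="literal")
        assert np.all(dR_lit[:, -1] > dR_closed[:, -1])
        assert np.allclose(dR_lit[:, :-1], dR_closed[:, :-1])


class TestIntegrate:
    def test_pure_diffusion_never_reaches_steady_state(self):
        # supply with no sink: total resource mass grows linearly at D_R*K
        c = es.Community(Y=np.ones(2), k=np.zeros((2, 2)),
                         A=np.zeros((2, 2)), m=np.full(2, 0.1))
        env = make_env(2, gamma=0.0, rho=0.0)
        grid = es.Grid1D(128, 100.0)
        s0 = es.initial_state(c, env, grid)
        st = IntegrationSettings(t_max=100.0)
        res = es.integrate(s0, c, env, grid, st)
        assert not res.converged
        ml = res.mass_ledger
        growth = ml.resource_mass[-1] - ml.resource_mass[0]
        assert np.allclose(growth, env.D_R * env.K * ml.t[-1], rtol=1e-6)
        assert np.allclose(ml.consumed[-1], 0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_abiotic_uniform_catalysts_match_bvp_oracle(self, seed):
        """gamma=0 steady state vs an independent boundary-value solve."""
        rng = np.random.default_rng(seed)
        kval = rng.uniform(0.2, 2.0)
        n0 = rng.uniform(0.05, 0.5)
        K = rng.uniform(0.5, 2.0)
        c = es.Community(Y=np.ones(1), k=np.array([[kval]]),
                         A=np.zeros((1, 1)), m=np.array([0.1]))
        env = es.EnvironmentParams(gamma=0.0, rho=0.0, K=np.array([K]))
        grid = es.Grid1D(256, 100.0)
        s0 = es.initial_state(c, env, grid, n0=n0)
        res = es.integrate(s0, c, env, grid)
        assert res.converged
        assert np.all(res.final_state.N == pytest.approx(n0))

        D_R = env.D_R

        def odes(x, y):
            return np.vstack([y[1], kval * n0 * y[0] / D_R])

        def bc(ya, yb):
            return np.array([ya[1] + (K - kval * n0 * ya[0]), yb[1]])

        guess = np.vstack([s0.R[0], np.gradient(s0.R[0], grid.x)])
        sol = solve_bvp(odes, bc, grid.x, guess, tol=1e-10, max_nodes=50000)
        assert sol.status == 0
        R_oracle = sol.sol(grid.x)[0]
        rel = (np.linalg.norm(res.final_state.R[0] - R_oracle)
               / np.linalg.norm(R_oracle))
        assert rel < 1e-3
        assert res.mass_ledger.balance_error() < 1e-3

    def test_small_negativity_is_clipped_large_aborts(self):
        c = es.sample_community(2, 2, 0.0, seed=0)
        env = make_env(2, gamma=0.0, rho=0.0)
        grid = es.Grid1D(64, 100.0)
        s0 = es.initial_state(c, env, grid)
        s0.R[0, -1] = -1e-10  # within clip_eps: silently zeroed
        res = es.integrate(s0, c, env, grid, IntegrationSettings(t_max=1.0))
        assert res.final_state.R.min() >= 0

        s_bad = es.initial_state(c, env, grid)
        s_bad.N[0, 0] = -1e-3
        with pytest.raises(NegativityError):
            es.integrate(s_bad, c, env, grid, IntegrationSettings(t_max=1.0))

    def test_literal_printed_right_boundary_blows_up_when_growing(self):
        c = es.sample_community(5, 5, 1.0, seed=0)
        env = make_env(5)
        grid = es.Grid1D(256, 100.0)
        s0 = es.initial_state(c, env, grid)
        st = IntegrationSettings(right_boundary="literal", t_max=100.0,
                                 store_ledger=False)
        with pytest.raises(NumericalBlowupError):
            es.integrate(s0, c, env, grid, st)

    def test_steady_state_independent_of_initial_biomass(self):
        """Order parameter unchanged when n0 varies +-50% (seed-0 scenario)."""
        ops = []
        c = es.sample_community(5, 5, 1.0, seed=0)
        env = make_env(5)
        grid = es.Grid1D(256, 100.0)
        for n0 in (0.05, 0.1, 0.15):
            s0 = es.initial_state(c, env, grid, n0=n0)
            res = es.integrate(s0, c, env, grid,
                               IntegrationSettings(store_ledger=False))
            assert res.converged
            rep = es.stratification_report(res.final_state.R, c.Y, grid)
            ops.append(rep.order_parameter)
        assert max(ops) - min(ops) < 0.01

    def test_nonnegative_final_state(self, saturated_ensemble):
        for run in saturated_ensemble[:5]:
            assert run["result"].final_state.N.min() >= 0
            assert run["result"].final_state.R.min() >= 0
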