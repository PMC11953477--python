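"""Spatial discretization and time integration to steady state.

The PDE system

    dN_i/dt = N_i (gamma g_i(R) - sum_{j!=i} A_ij N_j) + D_N d2N_i/dx2
    dR_a/dt = -sum_i f_ia(N, R) + D_R d2R_a/dx2

is discretized by the method of lines on a uniform grid with second-order
central differences.  Species obey no-flux (zero-gradient) Neumann
conditions at both ends.  Resources are supplied at x = 0 through the
gradient condition

    -dR_a/dx(0) = K_a - sum_i f_ia(0),

(supply flux reduced by boundary-layer consumption), implemented via a
ghost node that forces the centered gradient at the boundary to the
prescribed value.  The right boundary is closed by default
(``right_boundary="closed"``: dR_a/dx(L) = 0 — nothing leaves the system).
The alternative ``right_boundary="literal"`` prescribes
-dR_a/dx(L) = -sum_i f_ia(L) instead; note that this form injects resource
at x = L in proportion to the consumption there (a positive feedback), and
in growing regimes the run ends with a blow-up diagnostic.  A further
variant in which the prescribed quantity is the diffusive flux
-D_R dR/dx rather than the bare gradient (i.e. the conditions divided by
D_R) is available through ``flux_scaled_by_diffusion=True``; it amounts to
rescaling K.

With these ghosts the discrete resource mass (trapezoid quadrature) obeys
an exact semi-discrete balance:

    d/dt int R_a dx = D_R (K_a - F_a(0)) - int sum_i f_ia dx

(closed right boundary; the literal variant adds D_R F_a(L)), where
F_a(x) = sum_i f_ia at the boundary node.  The first term is what the
ledger records as supply, the second as consumption; the integrator's mass
ledger checks this balance over the whole run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .model import (Community, EnvironmentParams, Grid1D, SystemState,
                    growth_rate, total_consumption)

__all__ = [
    "IntegrationSettings",
    "MassLedger",
    "SimulationResult",
    "NumericalBlowupError",
    "NegativityError",
    "initial_state",
    "spatial_rhs",
    "integrate",
]


class NumericalBlowupError(RuntimeError):
    """A state magnitude exceeded the blow-up guard during integration."""


class NegativityError(RuntimeError):
    """A state entry fell below the negativity clipping tolerance."""


@dataclass(frozen=True)
class IntegrationSettings:
    """Controls for :func:`integrate`.

    t_max : time horizon (model time is in the same arbitrary units as L^2/D).
    steady_tol : steady state is declared when the max absolute time
        derivative over all fields and nodes drops below this.
    rtol, atol : solver tolerances passed to the stiff integrator.
    clip_eps : entries in (-clip_eps, 0) are clipped to zero at each
        checkpoint; anything below -clip_eps aborts the run.
    check_interval : model time between steady-state checks.
    ledger_dt : sampling interval for the mass ledger quadrature.
    """

    t_max: float = 1.0e4
    steady_tol: float = 1.0e-6
    rtol: float = 1.0e-6
    atol: float = 1.0e-9
    clip_eps: float = 1.0e-8
    check_interval: float = 10.0
    ledger_dt: float = 1.0
    right_boundary: str = "closed"
    flux_scaled_by_diffusion: bool = False
    store_trajectory: bool = False
    store_ledger: bool = True
    blowup_limit: float = 1.0e12

    def __post_init__(self):
        for name in ("t_max", "steady_tol", "rtol", "atol", "clip_eps",
                     "check_interval", "ledger_dt", "blowup_limit"):
            if not (float(getattr(self, name)) > 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.right_boundary not in ("closed", "literal"):
            raise ValueError("right_boundary must be 'closed' or 'literal'")


@dataclass
class MassLedger:
    """Time series of resource mass and cumulative boundary supply.

    All quantities are per resource (columns).  ``supplied`` and
    ``consumed`` are cumulative time integrals of the boundary supply rate
    D_R (K - F(0) + F(L)) and of the bulk consumption int sum_i f dx.
    """

    t: np.ndarray
    resource_mass: np.ndarray   # (nt, M)
    supplied: np.ndarray        # (nt, M)
    consumed: np.ndarray        # (nt, M)

    def balance_error(self) -> float:
        """Relative mass-balance closure at the final time.

        |supplied - dMass - consumed| over the largest of the three terms
        (totals over resources).  Cumulative supply can be small or negative
        when boundary consumption initially exceeds K, so the scale is the
        dominant term rather than supply alone.  Returns 0 for an empty
        ledger.
        """
        sup = float(self.supplied[-1].sum())
        dmass = float((self.resource_mass[-1] - self.resource_mass[0]).sum())
        con = float(self.consumed[-1].sum())
        scale = max(abs(sup), abs(dmass), abs(con))
        if scale == 0.0:
            return 0.0
        return abs(sup - dmass - con) / scale


@dataclass
class SimulationResult:
    final_state: SystemState
    converged: bool
    t_final: float
    residual: float
    trajectory: list[SystemState] | None = None
    mass_ledger: MassLedger | None = None


def initial_state(community: Community, env: EnvironmentParams,
                  grid: Grid1D, n0: float = 0.1) -> SystemState:
    """Homogeneous species and quadratically decaying resource profiles.

    Species start flat at density ``n0``.  Each resource starts at
    R_a(x) = K_a (L - x)^2 / (2 L): the unique decaying quadratic with
    R(L) = R'(L) = 0 whose inward gradient at the source matches the supply
    flux, -R'(0) = K_a, when boundary consumption is neglected.
    """
    if not (n0 > 0):
        raise ValueError("n0 must be positive")
    if env.K.shape != (community.M,):
        raise ValueError("env.K length does not match community.M")
    x = grid.x
    N = np.full((community.S, grid.n_nodes), float(n0))
    R = env.K[:, None] * (env.L - x[None, :]) ** 2 / (2.0 * env.L)
    return SystemState(N=N, R=R, t=0.0)


def _rhs_fields(N: np.ndarray, R: np.ndarray, community: Community,
                env: EnvironmentParams, grid: Grid1D,
                right_boundary: str = "closed",
                flux_scaled_by_diffusion: bool = False):
    """Vectorized RHS on (S, n) and (M, n) fields; returns (dN, dR, C).

    C is the local total consumption sum_i f_ia, reused by the ledger.
    """
    dx = grid.dx
    Np = np.maximum(N, 0.0)   # reaction terms see nonnegative fields
    Rp = np.maximum(R, 0.0)

    g = growth_rate(Rp, community)                      # (S, n)
    C = total_consumption(Np, Rp, community)            # (M, n)

    dN = Np * (env.gamma * g - community.A @ Np)
    dR = -C

    # species: zero-gradient ghosts at both ends
    lapN = np.empty_like(N)
    lapN[:, 1:-1] = N[:, :-2] - 2.0 * N[:, 1:-1] + N[:, 2:]
    lapN[:, 0] = 2.0 * (N[:, 1] - N[:, 0])
    lapN[:, -1] = 2.0 * (N[:, -2] - N[:, -1])
    dN += (env.D_N / dx ** 2) * lapN

    # resources: gradient boundary conditions via ghost nodes
    scale = env.D_R if flux_scaled_by_diffusion else 1.0
    grad0 = -(env.K - C[:, 0]) / scale      # prescribed dR/dx at x = 0
    if right_boundary == "closed":
        gradL = np.zeros(community.M)
    else:                                   # literal printed form
        gradL = C[:, -1] / scale
    lapR = np.empty_like(R)
    lapR[:, 1:-1] = R[:, :-2] - 2.0 * R[:, 1:-1] + R[:, 2:]
    lapR[:, 0] = 2.0 * (R[:, 1] - R[:, 0]) - 2.0 * dx * grad0
    lapR[:, -1] = 2.0 * (R[:, -2] - R[:, -1]) + 2.0 * dx * gradL
    dR += (env.D_R / dx ** 2) * lapR
    return dN, dR, C


def spatial_rhs(state: SystemState, community: Community,
                env: EnvironmentParams, grid: Grid1D,
                right_boundary: str = "closed",
                flux_scaled_by_diffusion: bool = False):
    """Full semi-discrete right-hand side (dN, dR) at one state."""
    if state.N.shape != (community.S, grid.n_nodes):
        raise ValueError("state.N shape does not match community/grid")
    if state.R.shape != (community.M, grid.n_nodes):
        raise ValueError("state.R shape does not match community/grid")
    if not (np.all(np.isfinite(state.N)) and np.all(np.isfinite(state.R))):
        raise ValueError("non-finite state entries")
    dN, dR, _ = _rhs_fields(state.N, state.R, community, env, grid,
                            right_boundary, flux_scaled_by_diffusion)
    return dN, dR


def _jac_sparsity(S: int, M: int, n: int) -> sparse.spmatrix:
    """Jacobian sparsity for y = [N.ravel(), R.ravel()] (field-major)."""
    I_n = sparse.identity(n, format="csr")
    T_n = sparse.diags([np.ones(n - 1), np.ones(n), np.ones(n - 1)],
                       [-1, 0, 1], format="csr")
    NN = sparse.kron(np.ones((S, S)), I_n) + sparse.kron(sparse.identity(S), T_n)
    NR = sparse.kron(np.ones((S, M)), I_n)
    RN = sparse.kron(np.ones((M, S)), I_n)
    RR = sparse.kron(np.ones((M, M)), I_n) + sparse.kron(sparse.identity(M), T_n)
    return sparse.bmat([[NN, NR], [RN, RR]], format="csr")


def integrate(state0: SystemState, community: Community,
              env: EnvironmentParams, grid: Grid1D,
              settings: IntegrationSettings | None = None) -> SimulationResult:
    """Advance the method-of-lines system to steady state or ``t_max``.

    Uses the BDF stiff integrator with a finite-difference Jacobian on the
    known sparsity pattern.  Every ``check_interval`` time units the max
    absolute time derivative is evaluated; the run stops once it falls below
    ``steady_tol`` (``converged=True``) or at ``t_max`` (``converged=False``,
    never an exception).  Blow-up beyond ``blowup_limit`` or negativity
    below ``-clip_eps`` raise with a diagnostic.
    """
    if settings is None:
        settings = IntegrationSettings()
    S, M, n = community.S, community.M, grid.n_nodes
    if state0.N.shape != (S, n) or state0.R.shape != (M, n):
        raise ValueError("state0 shapes do not match community/grid")

    fsd = settings.flux_scaled_by_diffusion
    rb = settings.right_boundary

    def rhs(t, y):
        N = y[:S * n].reshape(S, n)
        R = y[S * n:].reshape(M, n)
        dN, dR, _ = _rhs_fields(N, R, community, env, grid, rb, fsd)
        return np.concatenate([dN.ravel(), dR.ravel()])

    def clip_and_check(y, t):
        if np.any(np.abs(y) > settings.blowup_limit):
            raise NumericalBlowupError(
                f"state magnitude exceeded {settings.blowup_limit:g} "
                f"at t={t:g}")
        low = y.min()
        if low < -settings.clip_eps:
            raise NegativityError(
                f"state entry {low:.3e} below -clip_eps at t={t:g}")
        np.clip(y, 0.0, None, out=y)

    def residual_of(y):
        return float(np.max(np.abs(rhs(0.0, y))))

    sparsity = _jac_sparsity(S, M, n)
    y = np.concatenate([state0.N.ravel(), state0.R.ravel()])
    clip_and_check(y, state0.t)
    t = float(state0.t)

    trajectory = [SystemState(y[:S * n].reshape(S, n).copy(),
                              y[S * n:].reshape(M, n).copy(), t)] \
        if settings.store_trajectory else None

    ledger_t = [t]
    ledger_mass = [_mass_of(y, S, M, n, grid)]
    ledger_sup = [np.zeros(M)]
    ledger_con = [np.zeros(M)]

    converged = False
    residual = residual_of(y)
    if residual <= settings.steady_tol:
        converged = True

    # integrate in windows of several check intervals to limit solver
    # restart overhead while still honoring check_interval
    checks_per_window = 10
    while not converged and t < settings.t_max - 1e-12:
        window_end = min(t + checks_per_window * settings.check_interval,
                         settings.t_max)
        n_checks = max(1, int(round((window_end - t) / settings.check_interval)))
        t_eval = t + (window_end - t) * np.arange(1, n_checks + 1) / n_checks
        sol = solve_ivp(rhs, (t, window_end), y, method="BDF",
                        t_eval=t_eval, rtol=settings.rtol, atol=settings.atol,
                        jac_sparsity=sparsity,
                        dense_output=settings.store_ledger)
        if not sol.success:
            raise NumericalBlowupError(
                f"stiff integrator failed at t={t:g}: {sol.message}")

        if settings.store_ledger:
            _extend_ledger(sol, t, S, M, n, community, env, grid, rb, fsd,
                           settings.ledger_dt, ledger_t, ledger_mass,
                           ledger_sup, ledger_con)

        for idx in range(sol.y.shape[1]):
            yk = sol.y[:, idx].copy()
            tk = float(sol.t[idx])
            clip_and_check(yk, tk)
            if settings.store_trajectory:
                trajectory.append(SystemState(yk[:S * n].reshape(S, n).copy(),
                                              yk[S * n:].reshape(M, n).copy(),
                                              tk))
            res = residual_of(yk)
            if res <= settings.steady_tol:
                y, t, residual, converged = yk, tk, res, True
                break
        else:
            y = sol.y[:, -1].copy()
            t = float(sol.t[-1])
            clip_and_check(y, t)
            residual = residual_of(y)

    if settings.store_ledger and converged:
        # truncate ledger at the convergence time
        keep = np.searchsorted(np.asarray(ledger_t), t, side="right")
        ledger_t = ledger_t[:keep] + [t]
        ledger_mass = ledger_mass[:keep] + [_mass_of(y, S, M, n, grid)]
        ledger_sup = ledger_sup[:keep] + [ledger_sup[keep - 1]]
        ledger_con = ledger_con[:keep] + [ledger_con[keep - 1]]

    final = SystemState(y[:S * n].reshape(S, n), y[S * n:].reshape(M, n), t)
    ledger = None
    if settings.store_ledger:
        ledger = MassLedger(t=np.asarray(ledger_t),
                            resource_mass=np.vstack(ledger_mass),
                            supplied=np.vstack(ledger_sup),
                            consumed=np.vstack(ledger_con))
    return SimulationResult(final_state=final, converged=converged,
                            t_final=t, residual=residual,
                            trajectory=trajectory, mass_ledger=ledger)


def _mass_of(y, S, M, n, grid) -> np.ndarray:
    R = y[S * n:].reshape(M, n)
    return np.trapezoid(R, dx=grid.dx, axis=1)


def _supply_consumption_rates(y, S, M, n, community, env, grid, rb, fsd):
    N = np.maximum(y[:S * n].reshape(S, n), 0.0)
    R = np.maximum(y[S * n:].reshape(M, n), 0.0)
    C = total_consumption(N, R, community)
    boundary = env.K - C[:, 0]
    if rb == "literal":
        boundary = boundary + C[:, -1]
    supply = env.D_R * boundary / (env.D_R if fsd else 1.0)
    consumption = np.trapezoid(C, dx=grid.dx, axis=1)
    return supply, consumption


def _extend_ledger(sol, t0, S, M, n, community, env, grid, rb, fsd, ledger_dt,
                   ledger_t, ledger_mass, ledger_sup, ledger_con):
    """Accumulate cumulative supply/consumption over one solver window.

    Rates are sampled from the solver's dense output at the solver's own
    accepted step times (refined to at most ``ledger_dt``, with the
    checkpoint times included) and integrated with composite Simpson per
    interval, so the quadrature resolution follows the stiffness of the
    transient.  Checkpoints are appended at the solver's t_eval points.
    """
    t_end = float(sol.t[-1])
    steps = np.asarray(sol.sol.ts, dtype=float)
    knots = np.unique(np.concatenate([
        steps, np.asarray(sol.t, dtype=float),
        np.arange(t0, t_end, ledger_dt), [t0, t_end]]))
    knots = knots[(knots >= t0) & (knots <= t_end)]
    mids = 0.5 * (knots[:-1] + knots[1:])

    def rates_at(times):
        sup = np.empty((times.size, M))
        con = np.empty((times.size, M))
        for i, ti in enumerate(times):
            sup[i], con[i] = _supply_consumption_rates(
                sol.sol(ti), S, M, n, community, env, grid, rb, fsd)
        return sup, con

    sup_k, con_k = rates_at(knots)
    sup_m, con_m = rates_at(mids)
    h = np.diff(knots)[:, None]
    inc_sup = h / 6.0 * (sup_k[:-1] + 4.0 * sup_m + sup_k[1:])
    inc_con = h / 6.0 * (con_k[:-1] + 4.0 * con_m + con_k[1:])
    cum_sup = np.vstack([np.zeros(M), np.cumsum(inc_sup, axis=0)])
    cum_con = np.vstack([np.zeros(M), np.cumsum(inc_con, axis=0)])
    sup0 = ledger_sup[-1]
    con0 = ledger_con[-1]
    for idx in range(sol.y.shape[1]):
        tk = float(sol.t[idx])
        j = int(np.searchsorted(knots, tk))
        j = min(j, knots.size - 1)
        ledger_t.append(tk)
        ledger_mass.append(_mass_of(sol.y[:, idx], S, M, n, grid))
        ledger_sup.append(sup0 + cum_sup[j])
        ledger_con.append(con0 + cum_con[j])
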