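"""Core model objects for the spatial consumer-resource system.

The model tracks S reaction catalysts ("species") with densities N_i(x, t)
and M chemical resources with concentrations R_a(x, t) on a one-dimensional
domain x in [0, L].  Species grow by consuming resources (growth rate
g_i = sum_a Y_a k_ia R_a - m_i, scaled by the self-replication parameter
gamma), antagonize each other through a pairwise competition matrix A_ij,
and diffuse; resources are consumed at rate f_ia = k_ia R_a N_i, diffuse,
and are supplied at the x = 0 boundary.

This module holds the spatially local pieces: parameter containers, the
random community generator, and pointwise evaluation of growth, consumption
and reaction terms.  Spatial coupling (diffusion, boundary fluxes) lives in
:mod:`ecostrat.dynamics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "Community",
    "EnvironmentParams",
    "Grid1D",
    "SystemState",
    "sample_community",
    "growth_rate",
    "consumption_rate",
    "reaction_terms",
]


def _as_float_array(a, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class Community:
    """The biological content of one simulation.

    Parameters
    ----------
    Y : (M,) array
        Energy yield per unit of each resource (arbitrary energy units).
    k : (S, M) array
        Consumption rate constants; row i is species i's consumption
        profile.  The specialist default is the identity (k_ia = delta_ia).
    A : (S, S) array
        Pairwise competition strengths; A[i, j] is the per-capita inhibition
        of species i by species j.  Diagonal is zero (self-limitation enters
        only through maintenance and resource depletion).
    m : (S,) array
        Maintenance rates (baseline energy cost per capita).
    provenance : dict, optional
        Seed and sampler parameters when the community was drawn randomly.
    """

    Y: np.ndarray
    k: np.ndarray
    A: np.ndarray
    m: np.ndarray
    provenance: dict[str, Any] | None = field(default=None, compare=False)

    def __post_init__(self):
        Y = _as_float_array(self.Y, "Y", 1)
        k = _as_float_array(self.k, "k", 2)
        A = _as_float_array(self.A, "A", 2)
        m = _as_float_array(self.m, "m", 1)
        S, M = k.shape
        if Y.shape != (M,):
            raise ValueError(f"Y has length {Y.shape[0]}, expected M={M}")
        if A.shape != (S, S):
            raise ValueError(f"A has shape {A.shape}, expected ({S}, {S})")
        if m.shape != (S,):
            raise ValueError(f"m has length {m.shape[0]}, expected S={S}")
        if np.any(Y < 0) or np.any(k < 0) or np.any(m < 0) or np.any(A < 0):
            raise ValueError("Y, k, A, m must be elementwise nonnegative")
        if np.any(np.diag(A) != 0):
            raise ValueError("A must have a zero diagonal")
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "m", m)

    @property
    def S(self) -> int:
        return self.k.shape[0]

    @property
    def M(self) -> int:
        return self.k.shape[1]


@dataclass(frozen=True)
class EnvironmentParams:
    """Physical and global control parameters.

    gamma scales per-capita growth: gamma = 0 is abiotic catalysis, gamma > 0
    self-replicating life.  rho is the fraction of nonzero off-diagonal
    competition entries (kept here for provenance; it acts through the
    sampled A matrix).  K is the vector of constant resource supply fluxes
    at x = 0.
    """

    gamma: float
    rho: float
    K: np.ndarray
    D_N: float = 10.0
    D_R: float = 20.0
    L: float = 100.0

    def __post_init__(self):
        K = _as_float_array(np.atleast_1d(self.K), "K", 1)
        if np.any(K < 0):
            raise ValueError("K must be elementwise nonnegative")
        for name in ("gamma", "rho", "D_N", "D_R", "L"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
            object.__setattr__(self, name, v)
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.D_N <= 0 or self.D_R <= 0 or self.L <= 0:
            raise ValueError("D_N, D_R, L must be positive")
        object.__setattr__(self, "K", K)

    @classmethod
    def with_defaults(cls, M: int, gamma: float = 1.0, rho: float = 1.0,
                      K_value: float = 1.0, **kw) -> "EnvironmentParams":
        """Environment with all M supply fluxes equal to ``K_value``."""
        return cls(gamma=gamma, rho=rho, K=np.full(M, float(K_value)), **kw)


@dataclass(frozen=True)
class Grid1D:
    """Uniform discretization of [0, L]."""

    n_nodes: int
    L: float

    def __post_init__(self):
        if self.n_nodes < 8:
            raise ValueError("n_nodes must be >= 8")
        if self.L <= 0:
            raise ValueError("L must be positive")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.n_nodes)

    @property
    def dx(self) -> float:
        return self.L / (self.n_nodes - 1)


@dataclass
class SystemState:
    """Fields N_i(x) and R_a(x) on the grid at one instant."""

    N: np.ndarray  # (S, n_nodes)
    R: np.ndarray  # (M, n_nodes)
    t: float = 0.0

    def __post_init__(self):
        self.N = _as_float_array(self.N, "N", 2)
        self.R = _as_float_array(self.R, "R", 2)
        if self.N.shape[1] != self.R.shape[1]:
            raise ValueError("N and R must share the grid axis")

    def copy(self) -> "SystemState":
        return SystemState(self.N.copy(), self.R.copy(), self.t)


def sample_community(S: int, M: int, rho: float, seed,
                     y_range: tuple[float, float] = (0.0, 2.0),
                     a_mean: float = 0.4, a_sd: float = 0.1,
                     m_val: float = 0.1) -> Community:
    """Draw a random community at interaction density ``rho``.

    Energy yields Y_a are i.i.d. Uniform(y_range).  The consumption matrix
    is the specialist delta (``np.eye(S, M)``).  Exactly
    ``round(rho * S * (S - 1))`` ordered off-diagonal entries of A are made
    nonzero, chosen uniformly without replacement, each drawn from
    Normal(a_mean, a_sd); negative draws are truncated to zero (interactions
    are competitive).  The diagonal is zero.  The draw order (Y, then the
    entry selection, then the strengths) is fixed, so a given seed yields a
    bit-identical community.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    if S < 1 or M < 1:
        raise ValueError("S and M must be >= 1")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    for name, v in (("y_range", y_range), ("a_mean", a_mean),
                    ("a_sd", a_sd), ("m_val", m_val)):
        if not np.all(np.isfinite(np.asarray(v, dtype=float))):
            raise ValueError(f"{name} must be finite")
    rng = np.random.default_rng(seed)

    Y = rng.uniform(y_range[0], y_range[1], size=M)
    k = np.eye(S, M)
    m = np.full(S, float(m_val))

    n_slots = S * (S - 1)
    n_pick = int(round(rho * n_slots))
    if n_pick > n_slots:  # pragma: no cover - impossible for rho <= 1
        raise RuntimeError("requested more interactions than available slots")
    A = np.zeros((S, S))
    if n_pick > 0:
        flat = rng.choice(n_slots, size=n_pick, replace=False)
        strengths = np.maximum(rng.normal(a_mean, a_sd, size=n_pick), 0.0)
        # map slot index over ordered off-diagonal pairs to (i, j)
        i = flat // (S - 1)
        j = flat % (S - 1)
        j = np.where(j >= i, j + 1, j)
        A[i, j] = strengths

    seed_repr = seed if isinstance(seed, (int, np.integer)) else repr(seed)
    prov = {"seed": seed_repr,
            "sampler_params": {"S": S, "M": M, "rho": rho,
                               "y_range": list(y_range), "a_mean": a_mean,
                               "a_sd": a_sd, "m_val": m_val}}
    return Community(Y=Y, k=k, A=A, m=m, provenance=prov)


def growth_rate(R_local: np.ndarray, community: Community) -> np.ndarray:
    """Per-capita growth g_i = sum_a Y_a k_ia R_a - m_i at one location.

    ``R_local`` may be (M,) for one node or (M, n) for a batch of nodes;
    the result has matching trailing shape.
    """
    R_local = np.asarray(R_local, dtype=float)
    if R_local.shape[0] != community.M:
        raise ValueError("R_local length does not match community.M")
    return (community.k * community.Y) @ R_local - (
        community.m if R_local.ndim == 1 else community.m[:, None])


def consumption_rate(N_local: np.ndarray, R_local: np.ndarray,
                     community: Community) -> np.ndarray:
    """Consumption fluxes f_ia = k_ia R_a N_i at one location (S x M)."""
    N_local = np.asarray(N_local, dtype=float)
    R_local = np.asarray(R_local, dtype=float)
    if N_local.shape != (community.S,) or R_local.shape != (community.M,):
        raise ValueError("N_local / R_local shapes do not match community")
    return community.k * R_local[None, :] * N_local[:, None]


def total_consumption(N: np.ndarray, R: np.ndarray,
                      community: Community) -> np.ndarray:
    """Resource depletion sum_i f_ia, vectorized over nodes.

    ``N`` is (S,) or (S, n); ``R`` matches with leading dim M.  Returns the
    same trailing shape as ``R``.
    """
    return (community.k.T @ N) * R


def reaction_terms(state_at_node, community: Community,
                   env: EnvironmentParams):
    """Non-diffusive right-hand sides at one node.

    Returns ``(dN, dR)`` with dN_i = N_i (gamma g_i - sum_{j!=i} A_ij N_j)
    and dR_a = -sum_i f_ia.  No diffusion and no boundary supply: in the
    bulk, resources are only consumed.
    """
    N_local, R_local = state_at_node
    N_local = np.asarray(N_local, dtype=float)
    R_local = np.asarray(R_local, dtype=float)
    if not (np.all(np.isfinite(N_local)) and np.all(np.isfinite(R_local))):
        raise ValueError("non-finite state entries")
    g = growth_rate(R_local, community)
    dN = N_local * (env.gamma * g - community.A @ N_local)
    dR = -total_consumption(N_local, R_local, community)
    return dN, dR
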