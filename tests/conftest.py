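"""Shared fixtures: standard grids and the seeded replicate ensembles.

The session-scoped ensembles are the expensive pieces (stiff 1D
integrations at the standard 256-node resolution); they are computed once
and shared between the stratification, control and conservation tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import ecostrat as es
from ecostrat.dynamics import IntegrationSettings

N_REPLICATES = 20


@pytest.fixture(scope="session")
def grid():
    return es.Grid1D(n_nodes=256, L=100.0)


def run_replicate(seed: int, gamma: float, rho: float, n_nodes: int = 256,
                  settings: IntegrationSettings | None = None):
    """One standard-conditions replicate; returns (community, grid, result)."""
    community = es.sample_community(5, 5, rho, seed)
    env = es.EnvironmentParams.with_defaults(5, gamma=gamma, rho=rho)
    g = es.Grid1D(n_nodes=n_nodes, L=100.0)
    state0 = es.initial_state(community, env, g)
    result = es.integrate(state0, community, env, g,
                          settings or IntegrationSettings())
    return community, g, result


def _ensemble(gamma, rho, seeds):
    runs = []
    for seed in seeds:
        community, g, result = run_replicate(seed, gamma, rho)
        report = es.stratification_report(result.final_state.R, community.Y,
                                          g)
        runs.append({"seed": seed, "community": community, "grid": g,
                     "result": result, "report": report})
    return runs


@pytest.fixture(scope="session")
def saturated_ensemble():
    """20 replicates at gamma=1, rho=1 (seeds 0..19), standard conditions."""
    return _ensemble(1.0, 1.0, range(N_REPLICATES))


@pytest.fixture(scope="session")
def gamma0_ensemble():
    """Self-replication knockout: gamma=0 with full ecology (rho=1)."""
    return _ensemble(0.0, 1.0, range(N_REPLICATES))


@pytest.fixture(scope="session")
def rho0_ensemble():
    """Ecology knockout: rho=0 with full self-replication (gamma=1)."""
    return _ensemble(1.0, 0.0, range(N_REPLICATES))
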