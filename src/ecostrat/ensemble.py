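"""Seeded ensembles over the (gamma, rho) plane.

Each sweep cell fixes the self-replication scale gamma and the interaction
density rho, then runs ``n_replicates`` independent simulations: a fresh
random community per replicate, integrated from the standard initial
conditions to steady state, and summarized by its stratification order
parameter.  Replicate seeds are derived from the base seed by a stable mix
(``numpy.random.SeedSequence([base_seed, gamma_index, rho_index, r])``), so
any cell or replicate can be rerun in isolation and the full sweep is a
pure function of its spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import (IntegrationSettings, NegativityError,
                       NumericalBlowupError, initial_state, integrate)
from .metrics import stratification_report
from .model import EnvironmentParams, Grid1D, sample_community

__all__ = ["SweepSpec", "SweepResult", "replicate_seed", "run_cell",
           "run_sweep"]

DEFAULT_GRID_VALUES = (0.0, 0.25, 0.5, 0.75, 1.0)

RECORD_COLUMNS = ["gamma", "rho", "replicate", "seed", "order_parameter",
                  "converged", "n_valid_resources", "t_final", "residual",
                  "failed"]


@dataclass(frozen=True)
class SweepSpec:
    """Specification of a (gamma, rho) ensemble sweep."""

    gamma_values: tuple = DEFAULT_GRID_VALUES
    rho_values: tuple = DEFAULT_GRID_VALUES
    n_replicates: int = 10
    base_seed: int = 0
    S: int = 5
    M: int = 5
    D_N: float = 10.0
    D_R: float = 20.0
    L: float = 100.0
    K_value: float = 1.0
    n_nodes: int = 256
    n0: float = 0.1
    correlation_kind: str = "pearson"
    settings: IntegrationSettings = field(default_factory=IntegrationSettings)

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        vals = np.concatenate([np.asarray(self.gamma_values, dtype=float),
                               np.asarray(self.rho_values, dtype=float)])
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("gamma/rho values must be finite and >= 0")
        object.__setattr__(self, "gamma_values",
                           tuple(float(g) for g in self.gamma_values))
        object.__setattr__(self, "rho_values",
                           tuple(float(r) for r in self.rho_values))

    def grid(self) -> Grid1D:
        return Grid1D(n_nodes=self.n_nodes, L=self.L)

    def environment(self, gamma: float, rho: float) -> EnvironmentParams:
        return EnvironmentParams.with_defaults(
            self.M, gamma=gamma, rho=rho, K_value=self.K_value,
            D_N=self.D_N, D_R=self.D_R, L=self.L)


@dataclass
class SweepResult:
    """Per-run records plus per-cell summaries of a sweep."""

    records: pd.DataFrame
    summary: pd.DataFrame

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "SweepResult":
        grouped = records.groupby(["gamma", "rho"], sort=True)
        summary = grouped["order_parameter"].agg(
            mean="mean", sd="std", n_defined="count").reset_index()
        return cls(records=records.reset_index(drop=True), summary=summary)

    def cell_mean(self, gamma: float, rho: float) -> float:
        row = self.summary[(self.summary.gamma == gamma)
                           & (self.summary.rho == rho)]
        return float(row["mean"].iloc[0])


def replicate_seed(base_seed: int, gamma_index: int, rho_index: int,
                   replicate: int) -> int:
    """Stable per-replicate seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(gamma_index),
                                 int(rho_index), int(replicate)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_one(gamma: float, rho: float, seed: int, spec: SweepSpec) -> dict:
    """One replicate: sample -> integrate -> stratification report."""
    grid = spec.grid()
    community = sample_community(spec.S, spec.M, rho, seed)
    env = spec.environment(gamma, rho)
    state0 = initial_state(community, env, grid, n0=spec.n0)
    rec = {"gamma": gamma, "rho": rho, "seed": seed, "failed": False}
    try:
        result = integrate(state0, community, env, grid, spec.settings)
    except (NumericalBlowupError, NegativityError) as exc:
        rec.update(order_parameter=np.nan, converged=False,
                   n_valid_resources=0, t_final=np.nan, residual=np.nan,
                   failed=True, message=str(exc))
        return rec
    report = stratification_report(result.final_state.R, community.Y, grid,
                                   kind=spec.correlation_kind)
    rec.update(order_parameter=report.order_parameter,
               converged=result.converged,
               n_valid_resources=report.n_valid,
               t_final=result.t_final, residual=result.residual)
    return rec


def run_cell(gamma: float, rho: float, n_replicates: int, base_seed: int,
             spec: SweepSpec, gamma_index: int = 0,
             rho_index: int = 0) -> list[dict]:
    """All replicates of one (gamma, rho) cell, in replicate order.

    Replicates are independent (seeded individually) and produce identical
    records regardless of execution order.  Non-converged runs are recorded
    with ``converged=False`` and an order parameter computed from the final
    state anyway; numerical failures are flagged, never raised.
    """
    records = []
    for r in range(n_replicates):
        seed = replicate_seed(base_seed, gamma_index, rho_index, r)
        rec = run_one(gamma, rho, seed, spec)
        rec["replicate"] = r
        records.append(rec)
    return records


def run_sweep(spec: SweepSpec, progress: bool = False) -> SweepResult:
    """Run the full gamma x rho grid and summarize per-cell means.

    Cell means are taken over defined (non-NaN) order parameters only;
    ``n_defined`` in the summary counts them.
    """
    records = []
    for gi, gamma in enumerate(spec.gamma_values):
        for ri, rho in enumerate(spec.rho_values):
            if progress:
                print(f"sweep cell gamma={gamma:g} rho={rho:g}", flush=True)
            records.extend(run_cell(gamma, rho, spec.n_replicates,
                                    spec.base_seed, spec,
                                    gamma_index=gi, rho_index=ri))
    df = pd.DataFrame.from_records(records)
    cols = [c for c in RECORD_COLUMNS if c in df.columns] + \
        [c for c in df.columns if c not in RECORD_COLUMNS]
    return SweepResult.from_records(df[cols])
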