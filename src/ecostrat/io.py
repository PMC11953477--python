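"""File formats: CSV profile tables, JSON communities/reports, HDF5 results.

The profile table is the package's exchange format for concentration
profiles: a CSV with column ``x`` followed by one column per field, named
``N_1..N_S`` and ``R_1..R_M`` (metric-only use needs just the R columns).
Communities round-trip through a JSON document; full simulation results go
to HDF5 with the resolved parameters embedded, so every output file is
self-describing.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dynamics import IntegrationSettings, SimulationResult
from .metrics import StratificationReport
from .model import Community, EnvironmentParams, Grid1D, SystemState

__all__ = [
    "write_profiles_csv", "read_profiles_csv",
    "community_to_json", "community_from_json",
    "report_to_json", "save_result_hdf5",
    "sweep_to_csv",
]


def write_profiles_csv(path, x: np.ndarray, N: np.ndarray | None,
                       R: np.ndarray) -> None:
    """Write the profile table (columns x, N_1.., R_1..)."""
    data = {"x": np.asarray(x, dtype=float)}
    if N is not None:
        for i, row in enumerate(np.atleast_2d(N), start=1):
            data[f"N_{i}"] = row
    for a, row in enumerate(np.atleast_2d(R), start=1):
        data[f"R_{a}"] = row
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_profiles_csv(path):
    """Read a profile table; returns ``(x, N, R)`` (N may be empty 0-row)."""
    df = pd.read_csv(path)
    if "x" not in df.columns:
        raise ValueError(f"{path}: profile table must have an 'x' column")
    n_cols = sorted((c for c in df.columns if c.startswith("N_")),
                    key=lambda c: int(c[2:]))
    r_cols = sorted((c for c in df.columns if c.startswith("R_")),
                    key=lambda c: int(c[2:]))
    x = df["x"].to_numpy(dtype=float)
    N = df[n_cols].to_numpy(dtype=float).T if n_cols else np.empty((0, x.size))
    R = df[r_cols].to_numpy(dtype=float).T if r_cols else np.empty((0, x.size))
    return x, N, R


def community_to_json(community: Community, path=None) -> str:
    """Serialize a community; writes to ``path`` when given."""
    prov = community.provenance or {}
    doc = {
        "S": community.S, "M": community.M,
        "Y": community.Y.tolist(),
        "k": community.k.tolist(),
        "A": community.A.tolist(),
        "m": community.m.tolist(),
        "seed": prov.get("seed"),
        "sampler_params": prov.get("sampler_params"),
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def community_from_json(source) -> Community:
    """Inverse of :func:`community_to_json`; ``source`` is a path or str."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    doc = json.loads(text)
    prov = None
    if doc.get("seed") is not None or doc.get("sampler_params") is not None:
        prov = {"seed": doc.get("seed"),
                "sampler_params": doc.get("sampler_params")}
    return Community(Y=np.asarray(doc["Y"], dtype=float),
                     k=np.asarray(doc["k"], dtype=float),
                     A=np.asarray(doc["A"], dtype=float),
                     m=np.asarray(doc["m"], dtype=float),
                     provenance=prov)


def report_to_json(report: StratificationReport, path=None,
                   extra: dict | None = None) -> str:
    doc = report.to_dict()
    if extra:
        doc.update(extra)
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def save_result_hdf5(path, result: SimulationResult, community: Community,
                     env: EnvironmentParams, grid: Grid1D,
                     settings: IntegrationSettings,
                     config: dict | None = None) -> None:
    """Write a full run to HDF5: /state, /ledger, /meta.

    ``track_times=False`` keeps output byte-stable across reruns.
    """
    with h5py.File(path, "w", track_order=True) as f:
        st = f.create_group("state", track_order=True)
        for name, arr in (("N", result.final_state.N),
                          ("R", result.final_state.R),
                          ("x", grid.x)):
            st.create_dataset(name, data=arr, track_times=False)
        st.attrs["t"] = result.t_final

        if result.mass_ledger is not None:
            lg = f.create_group("ledger", track_order=True)
            ml = result.mass_ledger
            for name, arr in (("t", ml.t), ("resource_mass", ml.resource_mass),
                              ("supplied", ml.supplied),
                              ("consumed", ml.consumed)):
                lg.create_dataset(name, data=arr, track_times=False)
            lg.attrs["balance_error"] = ml.balance_error()

        meta = f.create_group("meta", track_order=True)
        meta.attrs["converged"] = result.converged
        meta.attrs["t_final"] = result.t_final
        meta.attrs["residual"] = result.residual
        meta.attrs["community_json"] = community_to_json(community)
        meta.attrs["environment_json"] = json.dumps(
            {"gamma": env.gamma, "rho": env.rho, "K": env.K.tolist(),
             "D_N": env.D_N, "D_R": env.D_R, "L": env.L})
        meta.attrs["grid_json"] = json.dumps(
            {"n_nodes": grid.n_nodes, "L": grid.L})
        meta.attrs["settings_json"] = json.dumps(asdict(settings))
        if config is not None:
            meta.attrs["config_json"] = json.dumps(config, default=str)


def sweep_to_csv(sweep_result, records_path, summary_path) -> None:
    sweep_result.records.to_csv(records_path, index=False,
                                float_format="%.12g")
    sweep_result.summary.to_csv(summary_path, index=False,
                                float_format="%.12g")
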