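"""Run configuration: YAML/JSON files resolved to model objects.

Unspecified fields take the standard parameterization (L=100, D_N=10,
D_R=20, m=0.1, specialist k, Y ~ U(0, 2), A ~ N(0.4, 0.1) at density rho,
K=1), so a minimal config only names what deviates from it.  Validation
happens before any computation; errors raise :class:`ConfigError` with the
offending field.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

from .dynamics import IntegrationSettings
from .ensemble import DEFAULT_GRID_VALUES, SweepSpec
from .model import Community, EnvironmentParams, Grid1D, sample_community

__all__ = ["ConfigError", "default_config", "load_config", "RunConfig"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


def default_config() -> dict:
    """The fully resolved default configuration as a plain dict."""
    return {
        "community": {
            "S": 5, "M": 5, "rho": 1.0, "seed": 0,
            "y_range": [0.0, 2.0], "a_mean": 0.4, "a_sd": 0.1,
            "m_val": 0.1,
            # explicit community JSON (overrides the sampler); relative to
            # the config file's directory
            "file": None,
        },
        "environment": {
            "gamma": 1.0, "D_N": 10.0, "D_R": 20.0, "L": 100.0,
            "K_value": 1.0,
        },
        "grid": {"n_nodes": 256},
        "initial": {"n0": 0.1},
        "integration": {
            "t_max": 1.0e4, "steady_tol": 1.0e-6, "rtol": 1.0e-6,
            "atol": 1.0e-9, "clip_eps": 1.0e-8, "check_interval": 10.0,
            "ledger_dt": 1.0, "right_boundary": "closed",
            "flux_scaled_by_diffusion": False, "store_trajectory": False,
            "store_ledger": True, "blowup_limit": 1.0e12,
        },
        "metrics": {"correlation_kind": "pearson"},
        "sweep": {
            "gamma_values": list(DEFAULT_GRID_VALUES),
            "rho_values": list(DEFAULT_GRID_VALUES),
            "n_replicates": 10, "base_seed": 0,
        },
    }


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config field: {where}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{where} must be a mapping")
            out[key] = _merge(base[key], val, where)
        else:
            out[key] = val
    return out


class RunConfig:
    """A validated configuration, resolvable to model objects."""

    def __init__(self, data: dict | None = None, base_dir=None):
        self.data = _merge(default_config(), data or {})
        self.base_dir = Path(base_dir) if base_dir is not None else Path(".")
        self._validate()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        try:
            text = path.read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        try:
            if path.suffix.lower() == ".json":
                data = json.loads(text)
            else:
                data = yaml.safe_load(text)
        except (json.JSONDecodeError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a mapping")
        return cls(data, base_dir=path.parent)

    def _validate(self):
        d = self.data
        try:
            self.integration_settings()
            env = self.environment()
            self.grid()
            comm = d["community"]
            if comm["S"] < 1 or comm["M"] < 1:
                raise ValueError("S and M must be >= 1")
            if not 0.0 <= float(comm["rho"]) <= 1.0:
                raise ValueError("community.rho must lie in [0, 1]")
            if not float(d["initial"]["n0"]) > 0:
                raise ValueError("initial.n0 must be positive")
            if d["metrics"]["correlation_kind"] not in ("pearson", "spearman"):
                raise ValueError("metrics.correlation_kind must be "
                                 "'pearson' or 'spearman'")
            if env.rho != float(comm["rho"]):  # pragma: no cover
                raise ValueError("inconsistent rho")
        except (ValueError, TypeError, KeyError) as exc:
            raise ConfigError(str(exc)) from exc

    # -- resolution to objects ------------------------------------------
    def community(self, seed_override=None) -> Community:
        c = self.data["community"]
        if c.get("file"):
            from .io import community_from_json
            return community_from_json(self.base_dir / c["file"])
        seed = c["seed"] if seed_override is None else seed_override
        return sample_community(int(c["S"]), int(c["M"]), float(c["rho"]),
                                int(seed), y_range=tuple(c["y_range"]),
                                a_mean=float(c["a_mean"]),
                                a_sd=float(c["a_sd"]),
                                m_val=float(c["m_val"]))

    def environment(self, M: int | None = None) -> EnvironmentParams:
        e = self.data["environment"]
        if M is None:
            M = int(self.data["community"]["M"])
        return EnvironmentParams.with_defaults(
            M, gamma=float(e["gamma"]),
            rho=float(self.data["community"]["rho"]),
            K_value=float(e["K_value"]), D_N=float(e["D_N"]),
            D_R=float(e["D_R"]), L=float(e["L"]))

    def grid(self) -> Grid1D:
        return Grid1D(n_nodes=int(self.data["grid"]["n_nodes"]),
                      L=float(self.data["environment"]["L"]))

    def integration_settings(self) -> IntegrationSettings:
        return IntegrationSettings(**{k: v for k, v in
                                      self.data["integration"].items()})

    def sweep_spec(self) -> SweepSpec:
        s = self.data["sweep"]
        e = self.data["environment"]
        return SweepSpec(
            gamma_values=tuple(s["gamma_values"]),
            rho_values=tuple(s["rho_values"]),
            n_replicates=int(s["n_replicates"]),
            base_seed=int(s["base_seed"]),
            S=int(self.data["community"]["S"]),
            M=int(self.data["community"]["M"]),
            D_N=float(e["D_N"]), D_R=float(e["D_R"]), L=float(e["L"]),
            K_value=float(e["K_value"]),
            n_nodes=int(self.data["grid"]["n_nodes"]),
            n0=float(self.data["initial"]["n0"]),
            correlation_kind=self.data["metrics"]["correlation_kind"],
            settings=self.integration_settings())

    def n0(self) -> float:
        return float(self.data["initial"]["n0"])

    def correlation_kind(self) -> str:
        return self.data["metrics"]["correlation_kind"]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=False)


def load_config(path) -> RunConfig:
    return RunConfig.from_file(path)
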