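"""Small generated inputs used by the test suite and for CLI smoke runs.

Everything here is synthetic and written programmatically: analytic-limit
configs (abiotic catalysts, pure supply + diffusion), the five-species
saturated-regime config, and hand-crafted profile tables whose penetration
depths are known in closed form (rectangle -> its own width, linear ramp ->
L/2, exponential -> its decay length).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .io import write_profiles_csv
from .model import Community
from .io import community_to_json

__all__ = ["write_fixtures", "reference_profiles"]

PROFILE_NODES = 1001
PROFILE_L = 100.0


def reference_profiles():
    """The three closed-form profiles on a 1001-node grid over [0, 100].

    Returns ``(x, R, expected_depths)``; R rows are rectangle (height 2,
    width 10; half-height at the jump node so the trapezoid area is exact),
    linear ramp (depth L/2 = 50), and exponential with decay length 5.
    """
    x = np.linspace(0.0, PROFILE_L, PROFILE_NODES)
    rect = np.where(x < 10.0, 2.0, 0.0)
    rect[np.isclose(x, 10.0)] = 1.0
    ramp = 2.0 * (1.0 - x / PROFILE_L)
    lam = 5.0
    expo = 1.5 * np.exp(-x / lam)
    depths = np.array([10.0, PROFILE_L / 2.0,
                       lam * (1.0 - np.exp(-PROFILE_L / lam))])
    return x, np.vstack([rect, ramp, expo]), depths


def write_fixtures(out_dir, seed: int = 0) -> dict:
    """Write all fixture files into ``out_dir``; returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    # five-species saturated-regime run
    fig_cfg = {"community": {"S": 5, "M": 5, "rho": 1.0, "seed": int(seed)},
               "environment": {"gamma": 1.0}}
    paths["saturated"] = out / "saturated_five_species.yaml"
    paths["saturated"].write_text(yaml.safe_dump(fig_cfg, sort_keys=False))

    # abiotic oracle: gamma=0, no interactions -> catalysts stay uniform,
    # resources relax to the linear reaction-diffusion steady state
    ab_cfg = {"community": {"S": 5, "M": 5, "rho": 0.0, "seed": int(seed)},
              "environment": {"gamma": 0.0}}
    paths["abiotic"] = out / "abiotic_oracle.yaml"
    paths["abiotic"].write_text(yaml.safe_dump(ab_cfg, sort_keys=False))

    # pure supply + diffusion: k = 0, no sink anywhere, no steady state
    comm = Community(Y=np.ones(2), k=np.zeros((2, 2)), A=np.zeros((2, 2)),
                     m=np.full(2, 0.1))
    paths["pure_diffusion_community"] = out / "pure_diffusion_community.json"
    community_to_json(comm, paths["pure_diffusion_community"])
    pd_cfg = {"community": {"S": 2, "M": 2, "rho": 0.0,
                            "file": "pure_diffusion_community.json"},
              "environment": {"gamma": 0.0},
              "integration": {"t_max": 100.0}}
    paths["pure_diffusion"] = out / "pure_diffusion.yaml"
    paths["pure_diffusion"].write_text(yaml.safe_dump(pd_cfg,
                                                      sort_keys=False))

    # hand-crafted profile table + energies for the metrics command
    x, R, depths = reference_profiles()
    paths["profiles"] = out / "reference_profiles.csv"
    write_profiles_csv(paths["profiles"], x, None, R)
    paths["energies"] = out / "reference_energies.json"
    paths["energies"].write_text(json.dumps({"Y": [1.0, 0.5, 2.0]}))
    paths["expected_depths"] = out / "reference_depths.json"
    paths["expected_depths"].write_text(json.dumps(
        {"depths": depths.tolist()}))
    return paths
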