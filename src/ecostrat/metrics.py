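"""Stratification metrics: penetration depth and the order parameter.

The penetration depth of a resource profile is the width of the rectangle
whose height equals the concentration at the source x = 0 and whose area
equals the area under the full profile — i.e. trapezoid area divided by the
source concentration.  The stratification order parameter of one simulated
community is the negative of the correlation between the resources'
penetration depths and their energy yields Y: +1 means resources are layered
in strictly decreasing order of usable energy (the energy-ordered pattern),
0 means energy has no bearing on spatial reach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import Grid1D, SystemState

__all__ = [
    "StratificationReport",
    "penetration_depth",
    "penetration_depths",
    "order_parameter",
    "stratification_report",
    "displacement_order",
]

DEPTH_FLOOR = 1.0e-9
EXTINCTION_FLOOR = 1.0e-9


@dataclass(frozen=True)
class StratificationReport:
    """Per-resource penetration depths plus the scalar order parameter.

    ``valid_mask`` flags resources whose depth is defined (source
    concentration above the floor).  ``order_parameter`` is NaN when fewer
    than two valid resources remain or either vector is constant.
    """

    depths: np.ndarray
    order_parameter: float
    valid_mask: np.ndarray
    correlation_kind: str = "pearson"

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def to_dict(self) -> dict:
        return {
            "depths": [None if not v else float(d)
                       for d, v in zip(self.depths, self.valid_mask)],
            "order_parameter": (None if np.isnan(self.order_parameter)
                                else float(self.order_parameter)),
            "valid_mask": [bool(v) for v in self.valid_mask],
            "correlation_kind": self.correlation_kind,
        }


def penetration_depth(profile: np.ndarray, grid: Grid1D,
                      depth_floor: float = DEPTH_FLOOR) -> float:
    """Area under the profile divided by its value at the source.

    Trapezoid quadrature on the grid.  Returns NaN (depth undefined) when
    the source concentration is at or below ``depth_floor``.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (grid.n_nodes,):
        raise ValueError("profile length does not match grid")
    if np.any(profile < 0):
        raise ValueError("profile must be nonnegative")
    if profile[0] <= depth_floor:
        return float("nan")
    area = np.trapezoid(profile, dx=grid.dx)
    return float(area / profile[0])


def penetration_depths(R: np.ndarray, grid: Grid1D,
                       depth_floor: float = DEPTH_FLOOR):
    """Depths and validity mask for an (M, n_nodes) stack of profiles."""
    R = np.asarray(R, dtype=float)
    depths = np.array([penetration_depth(r, grid, depth_floor) for r in R])
    return depths, ~np.isnan(depths)


def order_parameter(depths: np.ndarray, Y: np.ndarray,
                    valid_mask: np.ndarray | None = None,
                    kind: str = "pearson") -> float:
    """Negative correlation between penetration depths and energy yields.

    Pearson by default (Spearman available); restricted to valid entries.
    NaN when fewer than two valid entries remain or either vector has zero
    variance.
    """
    depths = np.asarray(depths, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if depths.shape != Y.shape:
        raise ValueError("depths and Y must have the same length")
    if valid_mask is None:
        valid_mask = ~np.isnan(depths)
    d = depths[valid_mask]
    y = Y[valid_mask]
    if d.size < 2 or np.ptp(d) == 0 or np.ptp(y) == 0:
        return float("nan")
    if kind == "pearson":
        r = stats.pearsonr(y, d).statistic
    elif kind == "spearman":
        r = stats.spearmanr(y, d).statistic
    else:
        raise ValueError(f"unknown correlation kind: {kind!r}")
    return float(-r)


def stratification_report(R: np.ndarray, Y: np.ndarray, grid: Grid1D,
                          kind: str = "pearson",
                          depth_floor: float = DEPTH_FLOOR
                          ) -> StratificationReport:
    """Full report (depths + order parameter) for a stack of profiles."""
    depths, mask = penetration_depths(R, grid, depth_floor)
    op = order_parameter(depths, Y, mask, kind=kind)
    return StratificationReport(depths=depths, order_parameter=op,
                                valid_mask=mask, correlation_kind=kind)


def displacement_order(state: SystemState, grid: Grid1D,
                       extinction_floor: float = EXTINCTION_FLOOR):
    """Species ranked by the position of their density maximum.

    Returns ``(ranking, unplaced)``: ``ranking`` lists surviving species
    indices sorted by arg-max position (ties broken by species index);
    ``unplaced`` lists species whose maximum density is below the
    extinction floor.
    """
    peaks = state.N.max(axis=1)
    argpos = grid.x[state.N.argmax(axis=1)]
    alive = peaks >= extinction_floor
    order = sorted(np.flatnonzero(alive), key=lambda i: (argpos[i], i))
    unplaced = list(np.flatnonzero(~alive))
    return [int(i) for i in order], [int(i) for i in unplaced]
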