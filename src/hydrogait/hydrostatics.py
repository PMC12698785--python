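"""Buoyancy-reduced apparent weight and the immersion/hypogravity mapping.

Over a full stride the mean vertical ground reaction force of steady
walking equals body weight; in water it equals the *apparent* weight, the
dry weight minus buoyancy.  The weight-bearing fraction w (apparent/dry
weight) is interpolated from a table of literature values indexed by
immersion depth as a fraction of stature, and doubles as the equivalent
gravity level (in g-units) of the immersion — walking immersed to the
xiphoid loads the body like walking at 0.33 g.

The default table is calibrated so that the four canonical landmark depths
(knee 28%, hip 48%, umbilicus 63%, xiphoid 73% of stature) map to 0.88,
0.58, 0.48 and 0.33 g; an alternative table can be supplied as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WeightBearingTable",
    "ImmersionState",
    "weight_bearing_fraction",
    "grf_vertical",
    "gravity_equivalent",
    "depth_from_gravity",
    "immersion_state",
]

DEFAULT_GRAVITY = 9.81  # m/s^2

#: (depth fraction of stature, weight-bearing fraction) calibration nodes.
DEFAULT_NODES = (
    (0.00, 1.00),
    (0.28, 0.88),  # knee
    (0.48, 0.58),  # hip
    (0.63, 0.48),  # umbilicus
    (0.73, 0.33),  # xiphoid
)

_MIN_FRACTION = 0.05  # floor applied when extrapolating past the last node


@dataclass(frozen=True)
class WeightBearingTable:
    """Piecewise-linear apparent-weight reduction vs relative depth."""

    depth_fractions: tuple
    weight_fractions: tuple

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_fractions, dtype=float)
        w = np.asarray(self.weight_fractions, dtype=float)
        if len(d) != len(w) or len(d) < 2:
            raise ValueError("table needs >= 2 (depth_fraction, fraction) pairs")
        if d[0] != 0.0 or w[0] != 1.0:
            raise ValueError("table must start at the dry-land point (0, 1.0)")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depth fractions must be strictly increasing")
        if np.any(np.diff(w) >= 0):
            raise ValueError("weight-bearing fractions must be strictly decreasing")
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("weight-bearing fractions must lie in (0, 1]")

    @classmethod
    def default(cls) -> "WeightBearingTable":
        d, w = zip(*DEFAULT_NODES)
        return cls(depth_fractions=d, weight_fractions=w)

    @classmethod
    def from_csv(cls, path) -> "WeightBearingTable":
        """Load nodes from a CSV with columns depth_fraction, weight_bearing_fraction."""
        df = pd.read_csv(path)
        return cls(
            depth_fractions=tuple(df["depth_fraction"].astype(float)),
            weight_fractions=tuple(df["weight_bearing_fraction"].astype(float)),
        )

    def interpolate(self, depth_fraction: float) -> float:
        d = np.asarray(self.depth_fractions, dtype=float)
        w = np.asarray(self.weight_fractions, dtype=float)
        x = float(depth_fraction)
        if x <= d[-1]:
            return float(np.interp(x, d, w))
        # continue the last segment's slope, floored away from zero
        slope = (w[-1] - w[-2]) / (d[-1] - d[-2])
        return float(max(w[-1] + slope * (x - d[-1]), _MIN_FRACTION))

    def inverse(self, weight_fraction: float) -> float:
        """Depth fraction at which the table gives ``weight_fraction``."""
        w = np.asarray(self.weight_fractions, dtype=float)
        d = np.asarray(self.depth_fractions, dtype=float)
        if not (w[-1] <= weight_fraction <= w[0]):
            raise ValueError(
                f"weight fraction {weight_fraction} outside table range "
                f"[{w[-1]}, {w[0]}]"
            )
        # table is strictly decreasing -> flip for np.interp
        return float(np.interp(weight_fraction, w[::-1], d[::-1]))


@dataclass(frozen=True)
class ImmersionState:
    """Hydrostatic loading state at one immersion depth."""

    depth: float  # m
    depth_fraction: float  # of stature
    weight_bearing_fraction: float  # w, dimensionless
    grf_vertical: float  # N, stride-mean vertical ground reaction force
    buoyancy: float  # N
    gravitational_force: float  # N
    gravity_equivalent: float  # g-units (== w)

    def __post_init__(self) -> None:
        if not 0 < self.weight_bearing_fraction <= 1:
            raise ValueError("weight-bearing fraction must lie in (0, 1]")
        if self.buoyancy < -1e-9:
            raise ValueError("buoyancy must be non-negative")


def weight_bearing_fraction(
    depth: float, stature: float, table: WeightBearingTable | None = None
) -> float:
    """Apparent-weight fraction w at an immersion depth (m)."""
    if table is None:
        table = WeightBearingTable.default()
    if depth < 0 or depth > stature:
        raise ValueError(f"depth must lie in [0, stature={stature}], got {depth}")
    return table.interpolate(depth / stature)


def grf_vertical(mass: float, w: float, g: float = DEFAULT_GRAVITY):
    """Stride-mean vertical GRF, buoyancy and dry weight (N).

    ``GRF_v = w * m * g``; buoyancy is the remainder of the dry weight, so
    ``B + GRF_v = Fg`` holds exactly.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if not 0 < w <= 1:
        raise ValueError(f"weight-bearing fraction must lie in (0, 1], got {w}")
    fg = mass * g
    grf = w * fg
    return grf, fg - grf, fg


def gravity_equivalent(w: float) -> float:
    """Equivalent gravity (g-units) of a weight-bearing fraction."""
    if not 0 < w <= 1:
        raise ValueError(f"weight-bearing fraction must lie in (0, 1], got {w}")
    return float(w)


def depth_from_gravity(
    g_frac: float, stature: float, table: WeightBearingTable | None = None
) -> float:
    """Immersion depth (m) that simulates ``g_frac`` of Earth gravity."""
    if table is None:
        table = WeightBearingTable.default()
    return table.inverse(g_frac) * stature


def immersion_state(
    depth: float,
    stature: float,
    mass: float,
    table: WeightBearingTable | None = None,
    g: float = DEFAULT_GRAVITY,
) -> ImmersionState:
    """Full hydrostatic state for one participant at one immersion depth."""
    w = weight_bearing_fraction(depth, stature, table)
    grf, buoyancy, fg = grf_vertical(mass, w, g)
    return ImmersionState(
        depth=depth,
        depth_fraction=depth / stature,
        weight_bearing_fraction=w,
        grf_vertical=grf,
        buoyancy=buoyancy,
        gravitational_force=fg,
        gravity_equivalent=w,
    )
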