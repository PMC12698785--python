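"""Strip-theory pressure drag on immersed body segments.

Each segment frustum is split into thin transverse strips; every strip
experiences a quadratic pressure drag driven by the velocity component
normal to the segment's long axis (the cross-flow principle — the axial
component is ignored, as usual for slender bodies).  A turbulent regime is
assumed, so the drag coefficient is a constant per segment class rather
than Reynolds-dependent; Reynolds numbers are still reported so the
assumption can be checked.  Wave and frictional drag are out of scope:
pressure drag dominates during immersed walking.

The frontal area of a strip is its diameter times its length, prorated by
the immersed fraction when the waterline crosses the strip; strips fully
above the surface contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body_model import SegmentFrustum, StripSet, discretize
from .gait_kinematics import SegmentKinematics, StrideMetrics

__all__ = [
    "WaterProperties",
    "DragSummary",
    "strip_drag",
    "segment_drag_series",
    "stride_drag",
]

DEFAULT_DENSITY = 995.7  # kg/m^3, water at 31-32 degC
DEFAULT_VISCOSITY = 7.7e-7  # m^2/s, kinematic, same temperature
DEFAULT_CD = {"limb": 1.0, "trunk": 1.0}  # circular cylinder, cross-flow


@dataclass(frozen=True)
class WaterProperties:
    """Fluid properties and immersion geometry for one trial."""

    surface_height: float  # m above the pool floor (= immersion depth)
    density: float = DEFAULT_DENSITY  # kg/m^3
    drag_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_CD))
    gravity: float = 9.81  # m/s^2
    kinematic_viscosity: float = DEFAULT_VISCOSITY  # m^2/s

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.surface_height < 0:
            raise ValueError("surface_height must be non-negative")
        if self.gravity <= 0:
            raise ValueError("gravity must be positive")
        if any(cd <= 0 for cd in self.drag_coefficients.values()):
            raise ValueError("drag coefficients must be positive")

    def cd_for(self, segment: SegmentFrustum) -> float:
        return float(self.drag_coefficients[segment.segment_class])


@dataclass(frozen=True)
class DragSummary:
    """Stride-level aggregate of the instantaneous drag force."""

    drf: float  # N, stride-representative drag force
    contact_drag: float  # N, mean |net horizontal drag| over contact samples
    swing_drag: float  # N, mean over swing samples
    per_segment: dict  # segment label -> mean |horizontal drag| contribution, N
    reynolds_range: tuple  # (min, max) over strips and frames
    aggregation: str  # "time_average" or "impulse_per_sl"

    def __post_init__(self) -> None:
        if self.drf < 0:
            raise ValueError("DrF must be non-negative")


def strip_drag(
    v_normal,
    local_radius,
    strip_length,
    immersed_fraction,
    water: WaterProperties,
    cd: float,
):
    """Instantaneous pressure-drag magnitude-with-sign on strips (N).

    ``F = 1/2 * rho * Cd * A * v_n * |v_n|`` with ``A = 2 r L * immersed
    fraction``.  The sign of the result follows the sign of ``v_normal``;
    the force opposing the motion is ``-F`` along the normal direction.
    """
    v_n = np.asarray(v_normal, dtype=float)
    if not np.all(np.isfinite(v_n)):
        raise ValueError("non-finite strip velocity")
    area = 2.0 * np.asarray(local_radius) * np.asarray(strip_length)
    area = area * np.clip(np.asarray(immersed_fraction, dtype=float), 0.0, 1.0)
    return 0.5 * water.density * cd * area * v_n * np.abs(v_n)


def segment_drag_series(
    kin: SegmentKinematics,
    strips: StripSet,
    water: WaterProperties,
    dt: float,
    phase_shift_samples: int = 0,
):
    """Per-frame net horizontal drag force (N) of one segment.

    Strip midpoint positions are reconstructed from the segment endpoints;
    strip velocities are time-derivatives of those positions, which keeps
    them exactly consistent with the marker-derived kinematics.  With
    ``phase_shift_samples`` the resulting *force series* is shifted half a
    stride (circularly), which synthesizes the unmarked contralateral limb
    of a periodic gait without introducing a wrap discontinuity into the
    differentiated positions.

    Returns ``(force_x, re_range)``: the per-frame summed horizontal force
    and the (min, max) strip Reynolds number.
    """
    prox = kin.prox
    dist = kin.dist
    vec = dist - prox
    length = np.hypot(vec[:, 0], vec[:, 1])[:, None]
    u = vec / length  # (n, 2) unit axis, prox -> dist

    frac = (strips.axial_position / strips.segment.length)[None, :, None]
    pos = prox[:, None, :] + frac * vec[:, None, :]  # (n, s, 2)
    vel = np.gradient(pos, dt, axis=0)  # (n, s, 2)

    # velocity component normal to the axis, in the sagittal plane
    v_axial = np.einsum("nsk,nk->ns", vel, u)
    v_norm_vec = vel - v_axial[..., None] * u[:, None, :]
    v_n = np.hypot(v_norm_vec[..., 0], v_norm_vec[..., 1])  # (n, s)

    # immersed fraction of each strip from its endpoint heights
    half = (strips.strip_length / 2.0)[None, :]
    y_mid = pos[..., 1]
    dy = np.abs(u[:, 1])[:, None] * half  # vertical half-extent of the strip
    y_low = y_mid - dy
    y_high = y_mid + dy
    span = np.maximum(y_high - y_low, 1e-12)
    immersed = np.clip((water.surface_height - y_low) / span, 0.0, 1.0)
    # strips lying horizontally: fully in or out by midpoint height
    flat = (y_high - y_low) < 1e-9
    immersed = np.where(flat, (y_mid <= water.surface_height).astype(float), immersed)

    cd = water.cd_for(strips.segment)
    area = 2.0 * strips.local_radius[None, :] * strips.strip_length[None, :] * immersed
    # drag opposes the normal velocity vector
    coef = 0.5 * water.density * cd * area * v_n  # N per unit normal velocity
    force_x = -(coef * v_norm_vec[..., 0]).sum(axis=1)
    if phase_shift_samples:
        force_x = np.roll(force_x, phase_shift_samples)

    re = v_n * (2.0 * strips.local_radius[None, :]) / water.kinematic_viscosity
    re_wet = re[immersed > 0]
    re_range = (
        (float(re_wet.min()), float(re_wet.max())) if re_wet.size else (0.0, 0.0)
    )
    return force_x, re_range


def stride_drag(
    states: dict,
    frusta: list,
    stride: StrideMetrics,
    water: WaterProperties,
    dt: float,
    n_strips: int = 20,
    aggregation: str = "time_average",
    include_contralateral: bool = True,
) -> DragSummary:
    """Aggregate strip drag over one stride into the stride force DrF.

    The instantaneous net horizontal drag of all segments (both legs — the
    contralateral limb is the measured one shifted by half a stride — plus
    the trunk) is averaged as a magnitude separately over the contact and
    swing windows of the stride and combined with duration weights, giving
    a stride-representative force in newtons.  ``aggregation`` may instead
    be ``"impulse_per_sl"``: the time integral of the force magnitude
    divided by the stride length.
    """
    if stride.stop - stride.start < 2:
        raise ValueError("empty stride window")
    if aggregation not in ("time_average", "impulse_per_sl"):
        raise ValueError(f"unknown aggregation {aggregation!r}")

    half = (stride.stop - stride.start) // 2
    window = slice(stride.start, stride.stop)

    n_frames = len(next(iter(states.values())).angle)
    total = np.zeros(n_frames)
    per_segment: dict[str, float] = {}
    re_lo, re_hi = np.inf, 0.0
    for frustum in frusta:
        if frustum.name not in states:
            continue
        kin = states[frustum.name]
        shift = half if (frustum.side == "left" and include_contralateral) else 0
        if frustum.side == "left" and not include_contralateral:
            continue
        strips = discretize(frustum, n_strips)
        force_x, (lo, hi) = segment_drag_series(
            kin, strips, water, dt, phase_shift_samples=shift
        )
        total += force_x
        label = f"{frustum.name}_{frustum.side}"
        per_segment[label] = float(np.mean(np.abs(force_x[window])))
        re_lo, re_hi = min(re_lo, lo), max(re_hi, hi)

    net = np.abs(total[window])
    contact = stride.contact_mask
    swing = ~contact
    contact_mean = float(net[contact].mean()) if contact.any() else 0.0
    swing_mean = float(net[swing].mean()) if swing.any() else 0.0
    n = len(net)
    weighted = (
        contact_mean * contact.sum() + swing_mean * swing.sum()
    ) / n  # == overall stride-time average of |net force|
    if aggregation == "time_average":
        drf = weighted
    else:
        drf = float(net.sum() * dt / stride.stride_length)

    return DragSummary(
        drf=float(drf),
        contact_drag=contact_mean,
        swing_drag=swing_mean,
        per_segment=per_segment,
        reynolds_range=(float(re_lo) if np.isfinite(re_lo) else 0.0, float(re_hi)),
        aggregation=aggregation,
    )
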