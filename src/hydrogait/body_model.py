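"""Segmented body geometry for drag integration.

Each lower-limb segment (foot, shank, thigh) and the trunk is modelled as a
conic frustum whose radii come from measured circumferences assuming a
circular cross-section.  Frusta are discretized into thin transverse strips
for strip-theory drag integration; the strip radius is the linearly
interpolated frustum radius at the strip midpoint, which makes the strip sum
of any linear-in-radius integrand exact at every strip count.

Head and arms are excluded: they stay above the water surface at every
immersion depth considered, and the drag model needs immersed geometry only.
Inertial parameters (masses, moments of inertia) are deliberately absent —
only geometry enters the drag computation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SEGMENT_NAMES",
    "SegmentDimensions",
    "Anthropometry",
    "SegmentFrustum",
    "StripSet",
    "build_segment_model",
    "discretize",
]

#: Segments carried by the geometric model, proximal landmark first.
SEGMENT_NAMES = ("foot", "shank", "thigh", "trunk")

#: Segments present on both sides of the body.
BILATERAL_SEGMENTS = ("foot", "shank", "thigh")

DEFAULT_N_STRIPS = 20


def _require_positive(value: float, name: str) -> None:
    if value is None or not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class SegmentDimensions:
    """Length and end circumferences of one body segment, in metres."""

    length: float
    proximal_circumference: float
    distal_circumference: float


@dataclass(frozen=True)
class Anthropometry:
    """Anthropometric measurements of one participant (SI units).

    ``leg_length`` is the greater-trochanter-to-floor distance used by the
    compass-gait estimate of the vertical centre-of-mass excursion.
    """

    participant_id: str
    mass: float  # kg
    stature: float  # m
    leg_length: float  # m
    segments: dict[str, SegmentDimensions] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require_positive(self.mass, "mass")
        _require_positive(self.stature, "stature")
        _require_positive(self.leg_length, "leg_length")
        if self.leg_length >= self.stature:
            raise ValueError(
                f"leg_length ({self.leg_length}) must be smaller than "
                f"stature ({self.stature})"
            )
        missing = [s for s in SEGMENT_NAMES if s not in self.segments]
        if missing:
            raise ValueError(f"missing segment measurements: {missing}")
        for name, dims in self.segments.items():
            _require_positive(dims.length, f"{name}.length")
            _require_positive(
                dims.proximal_circumference, f"{name}.proximal_circumference"
            )
            _require_positive(dims.distal_circumference, f"{name}.distal_circumference")

    @classmethod
    def from_dict(cls, payload: dict) -> "Anthropometry":
        """Build from a plain mapping (the JSON/YAML config schema).

        Expected keys: ``participant_id``, ``mass``, ``stature``,
        ``leg_length`` and ``segments`` — a mapping segment name ->
        ``{length, proximal_circumference, distal_circumference}`` (metres).
        """
        segments = {
            name: SegmentDimensions(**dims)
            for name, dims in payload.get("segments", {}).items()
        }
        return cls(
            participant_id=str(payload["participant_id"]),
            mass=float(payload["mass"]),
            stature=float(payload["stature"]),
            leg_length=float(payload["leg_length"]),
            segments=segments,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Anthropometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "mass": self.mass,
            "stature": self.stature,
            "leg_length": self.leg_length,
            "segments": {
                name: {
                    "length": d.length,
                    "proximal_circumference": d.proximal_circumference,
                    "distal_circumference": d.distal_circumference,
                }
                for name, d in self.segments.items()
            },
        }


@dataclass(frozen=True)
class SegmentFrustum:
    """A conic frustum approximating one body segment."""

    name: str
    length: float  # m
    proximal_radius: float  # m
    distal_radius: float  # m
    side: str = "axial"  # left | right | axial

    def __post_init__(self) -> None:
        _require_positive(self.length, f"{self.name}.length")
        _require_positive(self.proximal_radius, f"{self.name}.proximal_radius")
        _require_positive(self.distal_radius, f"{self.name}.distal_radius")
        if self.side not in ("left", "right", "axial"):
            raise ValueError(f"side must be left/right/axial, got {self.side!r}")

    def radius_at(self, axial_position):
        """Frustum radius at ``axial_position`` metres from the proximal end."""
        frac = np.asarray(axial_position, dtype=float) / self.length
        return self.proximal_radius + frac * (self.distal_radius - self.proximal_radius)

    @property
    def segment_class(self) -> str:
        """Drag-coefficient class: ``trunk`` or ``limb``."""
        return "trunk" if self.name == "trunk" else "limb"


@dataclass(frozen=True)
class StripSet:
    """Equal-length transverse strips of a frustum.

    ``axial_position`` holds strip *midpoints* measured from the proximal
    end; ``local_radius`` is the frustum radius evaluated there.
    """

    segment: SegmentFrustum
    axial_position: np.ndarray
    local_radius: np.ndarray
    strip_length: np.ndarray

    @property
    def n_strips(self) -> int:
        return len(self.axial_position)


def build_segment_model(
    anthro: Anthropometry, include_foot: bool = True
) -> list[SegmentFrustum]:
    """Convert anthropometrics into one frustum per segment per side.

    Radii follow from circumferences as ``r = c / (2*pi)``.  Foot, shank and
    thigh are built bilaterally (the contralateral side mirrors the measured
    one); the trunk is a single axial frustum between greater-trochanter and
    xiphoid level.  ``include_foot=False`` drops the foot frusta, for
    sensitivity checks on whether foot drag matters.
    """
    frusta: list[SegmentFrustum] = []
    for name in SEGMENT_NAMES:
        if name == "foot" and not include_foot:
            continue
        dims = anthro.segments[name]
        r_prox = dims.proximal_circumference / (2.0 * math.pi)
        r_dist = dims.distal_circumference / (2.0 * math.pi)
        sides = ("axial",) if name == "trunk" else ("right", "left")
        for side in sides:
            frusta.append(
                SegmentFrustum(
                    name=name,
                    length=dims.length,
                    proximal_radius=r_prox,
                    distal_radius=r_dist,
                    side=side,
                )
            )
    return frusta


def discretize(segment: SegmentFrustum, n_strips: int = DEFAULT_N_STRIPS) -> StripSet:
    """Split a frustum into ``n_strips`` equal-length strips.

    Midpoint evaluation of the linearly tapering radius makes the strip sum
    of the diameter integral exact for any strip count.
    """
    if n_strips < 1:
        raise ValueError(f"n_strips must be >= 1, got {n_strips}")
    h = segment.length / n_strips
    midpoints = (np.arange(n_strips) + 0.5) * h
    return StripSet(
        segment=segment,
        axial_position=midpoints,
        local_radius=np.asarray(segment.radius_at(midpoints)),
        strip_length=np.full(n_strips, h),
    )
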