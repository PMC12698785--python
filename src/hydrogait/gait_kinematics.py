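"""Sagittal-plane marker processing: ingestion, filtering, segment states,
and stride detection.

Conventions: x is horizontal in the walking direction (positive forward),
y is vertical, measured upward from the pool floor.  Segment angles are
measured from the vertical, positive when the distal end of a leg segment
(or the upper end of the trunk) lies forward of the proximal end.
Sampling is uniform, 60 Hz by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

__all__ = [
    "LANDMARKS",
    "SEGMENT_LANDMARKS",
    "MarkerTrajectorySet",
    "SegmentKinematics",
    "StrideMetrics",
    "read_markers",
    "lowpass_filter",
    "filter_markers",
    "segment_states",
    "detect_strides",
]

#: The seven digitized anatomical landmarks (right side of the body).
LANDMARKS = (
    "fifth_metatarsal",
    "calcaneus",
    "lateral_malleolus",
    "femoral_epicondyle",
    "greater_trochanter",
    "umbilicus",
    "xiphoid",
)

#: Segment -> (proximal landmark, distal landmark).  The trunk runs from the
#: greater trochanter up to the xiphoid; its "distal" end is the upper one.
SEGMENT_LANDMARKS = {
    "foot": ("calcaneus", "fifth_metatarsal"),
    "shank": ("femoral_epicondyle", "lateral_malleolus"),
    "thigh": ("greater_trochanter", "femoral_epicondyle"),
    "trunk": ("greater_trochanter", "xiphoid"),
}

DEFAULT_SAMPLING_RATE = 60.0
DEFAULT_CUTOFF = 4.5  # Hz, midpoint of the 4-5 Hz range used for slow gait
DEFAULT_FILTER_ORDER = 2
MAX_GAP_SAMPLES = 3

# Foot-contact predicate thresholds (configurable through detect_strides)
CONTACT_HEIGHT = 0.02  # m above the floor
CONTACT_SPEED = 0.05  # m/s horizontal marker speed
MIN_EVENT_DURATION = 0.15  # s; contact runs/gaps shorter than this are noise


@dataclass(frozen=True)
class MarkerTrajectorySet:
    """Uniformly sampled 2-D trajectories of the seven landmarks."""

    sampling_rate: float  # Hz
    time: np.ndarray  # s
    data: pd.DataFrame  # columns "<landmark>_x", "<landmark>_y"

    def __post_init__(self) -> None:
        missing = [
            lm
            for lm in LANDMARKS
            if f"{lm}_x" not in self.data.columns or f"{lm}_y" not in self.data.columns
        ]
        if missing:
            raise ValueError(f"missing landmark columns for: {missing}")
        if len(self.time) != len(self.data):
            raise ValueError("time vector and data length mismatch")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def xy(self, landmark: str) -> np.ndarray:
        """(n, 2) array of the landmark positions."""
        return self.data[[f"{landmark}_x", f"{landmark}_y"]].to_numpy()

    def x(self, landmark: str) -> np.ndarray:
        return self.data[f"{landmark}_x"].to_numpy()

    def y(self, landmark: str) -> np.ndarray:
        return self.data[f"{landmark}_y"].to_numpy()

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "time", self.time)
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class SegmentKinematics:
    """Time series describing one segment's planar motion.

    ``angle`` is measured from the vertical (rad, unwrapped);
    ``angular_velocity`` is its central-difference derivative.  Proximal and
    distal endpoint positions and the proximal endpoint velocity are kept so
    the drag integrator can reconstruct every strip's position and velocity.
    """

    name: str
    prox: np.ndarray  # (n, 2) m
    dist: np.ndarray  # (n, 2) m
    angle: np.ndarray  # rad from vertical
    angular_velocity: np.ndarray  # rad/s
    prox_velocity: np.ndarray  # (n, 2) m/s


@dataclass(frozen=True)
class StrideMetrics:
    """Spatiotemporal description of one detected stride."""

    stride_index: int
    start: int  # sample index of initial foot contact
    stop: int  # sample index of the next initial contact (exclusive)
    stride_length: float  # m, trochanter forward displacement
    duration: float  # s
    speed: float  # m/s, stride_length / duration
    contact_mask: np.ndarray  # bool per sample in [start, stop)
    single_support_displacement: float  # m, L_sc

    def __post_init__(self) -> None:
        if self.stride_length <= 0:
            raise ValueError("stride_length must be positive")
        if abs(self.speed * self.duration - self.stride_length) > 1e-6 * max(
            self.stride_length, 1.0
        ):
            raise ValueError("speed * duration must equal stride_length")


def read_markers(path, sampling_rate: float | None = None) -> MarkerTrajectorySet:
    """Read a marker CSV (``time`` + ``<landmark>_x/_y`` columns).

    Gaps (missing cells) of at most three consecutive samples are linearly
    interpolated and logged; longer gaps are rejected.  Time must be
    monotone and uniformly sampled.
    """
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError("marker file must contain a 'time' column")
    missing = [
        lm for lm in LANDMARKS if f"{lm}_x" not in df.columns or f"{lm}_y" not in df.columns
    ]
    if missing:
        raise ValueError(f"marker file missing landmark columns: {missing}")

    t = df["time"].to_numpy(dtype=float)
    dts = np.diff(t)
    if len(t) < 2 or np.any(dts <= 0):
        raise ValueError("time column must be strictly increasing")
    if np.ptp(dts) > 1e-6 * np.mean(dts) + 1e-9:
        raise ValueError("non-uniform sampling detected in time column")
    fs = sampling_rate if sampling_rate is not None else 1.0 / np.mean(dts)

    cols = [f"{lm}_{ax}" for lm in LANDMARKS for ax in ("x", "y")]
    data = df[cols].astype(float)
    for col in cols:
        series = data[col]
        if series.isna().any():
            gap_lengths = _nan_run_lengths(series.to_numpy())
            if gap_lengths.max() > MAX_GAP_SAMPLES:
                raise ValueError(
                    f"column {col} has a gap of {gap_lengths.max()} samples "
                    f"(> {MAX_GAP_SAMPLES}); trial rejected"
                )
            log.info(
                "interpolated %d missing sample(s) in %s", int(series.isna().sum()), col
            )
            data[col] = series.interpolate(method="linear", limit_direction="both")
    return MarkerTrajectorySet(sampling_rate=float(fs), time=t, data=data)


def _nan_run_lengths(values: np.ndarray) -> np.ndarray:
    isnan = np.isnan(values)
    if not isnan.any():
        return np.array([0])
    edges = np.diff(np.concatenate(([0], isnan.astype(int), [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return stops - starts


def lowpass_filter(
    series: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter (forward-backward).

    Raises if ``cutoff`` is at or above the Nyquist frequency.
    """
    nyquist = sampling_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={nyquist} Hz), got {cutoff} Hz"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=sampling_rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float))


def filter_markers(
    markers: MarkerTrajectorySet,
    cutoff: float = DEFAULT_CUTOFF,
    order: int = DEFAULT_FILTER_ORDER,
) -> MarkerTrajectorySet:
    """Apply the zero-phase low-pass filter to every marker coordinate."""
    filtered = markers.data.apply(
        lambda col: lowpass_filter(col.to_numpy(), cutoff, markers.sampling_rate, order)
    )
    return replace(markers, data=filtered)


def _angle_from_vertical(vec: np.ndarray, points_up: bool) -> np.ndarray:
    # For leg segments the prox->dist vector points downward; measure the
    # deviation from straight down.  The trunk vector points upward.
    if points_up:
        raw = np.arctan2(vec[:, 0], vec[:, 1])
    else:
        raw = np.arctan2(vec[:, 0], -vec[:, 1])
    return np.unwrap(raw)


def segment_states(
    markers: MarkerTrajectorySet, segments=tuple(SEGMENT_LANDMARKS)
) -> dict[str, SegmentKinematics]:
    """Derive per-segment angles, angular velocities and endpoint velocities.

    Velocities are central differences (one-sided at the ends).  A frame in
    which the two bounding landmarks coincide (zero-length segment) is
    rejected — it would make the orientation undefined.
    """
    dt = markers.dt
    out: dict[str, SegmentKinematics] = {}
    for name in segments:
        prox_lm, dist_lm = SEGMENT_LANDMARKS[name]
        prox = markers.xy(prox_lm)
        dist = markers.xy(dist_lm)
        vec = dist - prox
        lengths = np.hypot(vec[:, 0], vec[:, 1])
        if np.any(lengths < 1e-9):
            bad = int(np.argmax(lengths < 1e-9))
            raise ValueError(
                f"segment {name!r} has coincident landmarks at frame {bad}"
            )
        angle = _angle_from_vertical(vec, points_up=(name == "trunk"))
        out[name] = SegmentKinematics(
            name=name,
            prox=prox,
            dist=dist,
            angle=angle,
            angular_velocity=np.gradient(angle, dt),
            prox_velocity=np.gradient(prox, dt, axis=0),
        )
    return out


def _contact_mask(
    markers: MarkerTrajectorySet,
    landmark: str,
    floor_height: float,
    contact_height: float,
    contact_speed: float,
) -> np.ndarray:
    y = markers.y(landmark)
    vx = np.gradient(markers.x(landmark), markers.dt)
    return (y < floor_height + contact_height) & (np.abs(vx) < contact_speed)


def _debounce(mask: np.ndarray, min_samples: int) -> np.ndarray:
    """Suppress contact gaps, then contact runs, shorter than ``min_samples``
    (morphological closing followed by opening)."""
    if min_samples <= 1:
        return mask
    out = mask.copy()
    for target in (False, True):  # close gaps first, then drop short runs
        edges = np.diff(np.concatenate(([0], (out == target).astype(int), [0])))
        starts = np.flatnonzero(edges == 1)
        stops = np.flatnonzero(edges == -1)
        for lo, hi in zip(starts, stops):
            if hi - lo < min_samples and lo > 0 and hi < len(out):
                out[lo:hi] = not target
    return out


def detect_strides(
    markers: MarkerTrajectorySet,
    floor_height: float = 0.0,
    contact_height: float = CONTACT_HEIGHT,
    contact_speed: float = CONTACT_SPEED,
    min_event_duration: float = MIN_EVENT_DURATION,
) -> list[StrideMetrics]:
    """Delimit strides from calcaneus contact to the next calcaneus contact.

    A foot is "in contact" when its calcaneus sits below ``floor_height +
    contact_height`` and moves slower than ``contact_speed`` horizontally —
    standard thresholds for slow walking.  Contact runs or gaps shorter
    than ``min_event_duration`` are treated as digitization noise and
    suppressed before events are extracted.  Stride length is the greater
    trochanter's forward displacement over the stride; ``L_sc`` is its
    displacement during single support, where single support is estimated
    from the measured foot and a contralateral contact pattern shifted by
    half a stride (only one side of the body carries markers).
    """
    contact = _contact_mask(
        markers, "calcaneus", floor_height, contact_height, contact_speed
    )
    contact = _debounce(contact, int(round(min_event_duration * markers.sampling_rate)))
    onsets = np.flatnonzero(np.diff(contact.astype(int)) == 1) + 1
    if contact[0]:
        onsets = np.concatenate(([0], onsets))
    if len(onsets) < 2:
        raise ValueError("no strides: fewer than two foot contacts detected")

    troch_x = markers.x("greater_trochanter")
    dt = markers.dt
    strides: list[StrideMetrics] = []
    for k, (i0, i1) in enumerate(zip(onsets[:-1], onsets[1:])):
        sl = float(troch_x[i1] - troch_x[i0])
        duration = float((i1 - i0) * dt)
        if sl <= 1e-6:
            continue
        half = (i1 - i0) // 2
        contra = np.roll(contact, half)
        window = slice(i0, i1)
        single = contact[window] & ~contra[window]
        l_sc = _single_support_displacement(troch_x[window], single)
        strides.append(
            StrideMetrics(
                stride_index=k,
                start=int(i0),
                stop=int(i1),
                stride_length=sl,
                duration=duration,
                speed=sl / duration,
                contact_mask=contact[window].copy(),
                single_support_displacement=l_sc,
            )
        )
    if not strides:
        raise ValueError("no strides: no forward progression between contacts")
    return strides


def _single_support_displacement(troch_x: np.ndarray, single: np.ndarray) -> float:
    """Trochanter forward displacement over the longest single-support run."""
    if not single.any():
        return 0.0
    edges = np.diff(np.concatenate(([0], single.astype(int), [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    lengths = stops - starts
    j = int(np.argmax(lengths))
    lo, hi = starts[j], min(stops[j], len(troch_x) - 1)
    return float(troch_x[hi] - troch_x[lo])
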