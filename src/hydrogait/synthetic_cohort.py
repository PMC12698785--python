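"""Synthetic study generator: anthropometrics, gait kinematics, and
breath-by-breath gas exchange with known ground truth.

The generator emulates the study conditions end to end: nine adults
(mass 77.1 +/- 9.8 kg, stature 1.78 +/- 0.04 m), four landmark immersion
depths, four nominal speeds, five analyzed strides per condition, 60 Hz
sagittal marker trajectories with Gaussian digitization noise, and
breath-by-breath VO2/VCO2 series whose underlying net cost equals a known
cost-of-transport field (by default the published quadratic surface).
Every generator is a pure function of (config, seed), so each pipeline
stage can be tested against exact ground truth without any recording.

The gait waveform is a compass-style template: the hip translates at the
requested speed and rides on the stance-leg strut, the ankle alternates
stance (fixed on the floor) and a cycloidal swing, and the knee follows by
two-link inverse kinematics.  Only stride-integrated quantities (stride
length, phase timing, segment velocities) matter downstream, so the
template does not attempt subject-specific joint-angle realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference
from .body_model import Anthropometry, SegmentDimensions
from .energetics import CalorimetryRecord, energy_equivalent_garby_astrup
from .gait_kinematics import LANDMARKS, MarkerTrajectorySet
from .hydrostatics import WeightBearingTable, grf_vertical, weight_bearing_fraction

__all__ = ["CohortConfig", "generate_cohort", "generate_gait_trial",
           "generate_metabolic_data", "stride_length_for_speed"]

#: Segment lengths as fractions of stature (standard anthropometric ratios;
#: trunk is greater-trochanter to xiphoid level).
LENGTH_FRACTIONS = {"foot": 0.152, "shank": 0.246, "thigh": 0.245, "trunk": 0.20}
LEG_LENGTH_FRACTION = 0.53

#: Baseline circumferences (m) for a 77.1 kg / 1.78 m adult male.
BASE_CIRCUMFERENCES = {
    "foot": (0.25, 0.23),
    "shank": (0.37, 0.23),
    "thigh": (0.58, 0.39),
    "trunk": (0.96, 0.90),
}

ANKLE_HEIGHT = 0.07  # m, malleolus above the floor
DUTY_FACTOR = 0.65  # stance fraction of the stride, slow walking
SWING_LIFT = 0.06  # m, peak ankle lift during swing
KNEE_SLACK = 0.93  # effective strut length as fraction of thigh+shank
REST_GROSS_POWER = 70.0  # J/kg/min, ~1 MET standing baseline


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_participants: int = 9
    seed: int = 0
    mass_mean: float = reference.COHORT_MASS[0]
    mass_sd: float = reference.COHORT_MASS[1]
    stature_mean: float = reference.COHORT_STATURE[0]
    stature_sd: float = reference.COHORT_STATURE[1]
    depths: tuple = tuple(reference.STUDY_DEPTHS.values())
    speeds: tuple = reference.NOMINAL_SPEEDS
    strides_per_condition: int = 5
    marker_noise_sd: float = 0.005  # m, manual-digitization jitter
    metabolic_noise_cv: float = 0.05  # multiplicative, per breath
    efficiency: float = 0.25
    sampling_rate: float = 60.0
    surface_coefficients: tuple = reference.SURFACE_COEFFICIENTS
    rer_band: tuple = reference.RER_BAND
    walk_duration: float = 300.0  # s, 5-min trials
    rest_duration: float = 420.0  # s, 7-min standing baseline
    breath_interval: float = 3.0  # s
    #: Source of the "true" measured cost the metabolic generator encodes:
    #: "forward_model" (each participant's own mechanical prediction, the
    #: default — measured and predicted cost then agree up to noise) or
    #: "surface" (the published quadratic COT field, used when the study's
    #: absolute cost levels are the quantity being emulated or recovered).
    cot_source: str = "forward_model"

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("mass_sd", "stature_sd", "marker_noise_sd", "metabolic_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cot_source not in ("forward_model", "surface"):
            raise ValueError(f"unknown cot_source {self.cot_source!r}")


def _true_cot(config: CohortConfig, speed: float, depth: float) -> float:
    a_ss, a_dd, a_sd, a_s, a_d, a0 = config.surface_coefficients
    return (
        a_ss * speed**2 + a_dd * depth**2 + a_sd * speed * depth
        + a_s * speed + a_d * depth + a0
    )


def stride_length_for_speed(speed: float, stature: float) -> float:
    """Target stride length (m): slow immersed walking shortens strides."""
    return (0.5 + 0.5 * speed) * (stature / 1.78)


def _truncated_normal(rng, mean, sd, n, n_sigma=3.0):
    out = rng.normal(mean, sd, size=n)
    while True:
        bad = np.abs(out - mean) > n_sigma * sd
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def generate_cohort(config: CohortConfig):
    """Draw the cohort's anthropometrics and the ground-truth skeleton.

    Returns ``(participants, truth)``: a list of :class:`Anthropometry`
    (segment dimensions scaled allometrically from stature and mass,
    masses truncated at +/-3 SD) and a DataFrame with one row per
    participant x depth x speed carrying the generator's truth — stride
    length, weight-bearing fraction, stride-mean vertical GRF, and the
    quadratic-surface cost field value (``true_cot``), which the metabolic
    generator encodes when ``cot_source == "surface"``.
    """
    rng = np.random.default_rng(config.seed)
    masses = _truncated_normal(rng, config.mass_mean, config.mass_sd,
                               config.n_participants)
    statures = _truncated_normal(rng, config.stature_mean, config.stature_sd,
                                 config.n_participants)
    participants = []
    for i, (m, h) in enumerate(zip(masses, statures)):
        girth_scale = np.sqrt((m / h) / (config.mass_mean / config.stature_mean))
        segments = {
            name: SegmentDimensions(
                length=LENGTH_FRACTIONS[name] * h,
                proximal_circumference=BASE_CIRCUMFERENCES[name][0] * girth_scale,
                distal_circumference=BASE_CIRCUMFERENCES[name][1] * girth_scale,
            )
            for name in LENGTH_FRACTIONS
        }
        participants.append(
            Anthropometry(
                participant_id=f"P{i + 1:02d}",
                mass=float(m),
                stature=float(h),
                leg_length=LEG_LENGTH_FRACTION * h,
                segments=segments,
            )
        )

    table = WeightBearingTable.default()
    rows = []
    for p in participants:
        for depth in config.depths:
            w = weight_bearing_fraction(depth, p.stature, table)
            grf, buoyancy, fg = grf_vertical(p.mass, w)
            for speed in config.speeds:
                rows.append(
                    {
                        "participant_id": p.participant_id,
                        "mass": p.mass,
                        "stature": p.stature,
                        "depth": depth,
                        "speed": speed,
                        "true_stride_length": stride_length_for_speed(speed, p.stature),
                        "true_weight_bearing": w,
                        "true_grf_v": grf,
                        "true_cot": _true_cot(config, speed, depth),
                    }
                )
    return participants, pd.DataFrame(rows)


def _ankle_trajectory(t, t_strikes, stride_length, duration, duty):
    """Piecewise stance/cycloidal-swing ankle path, vectorized over frames."""
    t0 = t_strikes[0]
    m = np.clip(np.floor((t - t0) / duration).astype(int), 0, len(t_strikes) - 2)
    phase = (t - (t0 + m * duration)) / duration
    phase = np.clip(phase, 0.0, 1.0)
    x_st = m * stride_length
    swing = phase >= duty
    tau = np.where(swing, (phase - duty) / (1.0 - duty), 0.0)
    dx = stride_length * (tau - np.sin(2 * np.pi * tau) / (2 * np.pi))
    x = x_st + np.where(swing, dx, 0.0)
    y = ANKLE_HEIGHT + np.where(swing, SWING_LIFT * np.sin(np.pi * tau) ** 2, 0.0)
    return x, y


def generate_gait_trial(
    participant: Anthropometry,
    depth: float,
    speed: float,
    config: CohortConfig,
    seed: int,
    n_strides: int | None = None,
    stride_length: float | None = None,
) -> MarkerTrajectorySet:
    """Synthesize a 60 Hz marker trial at one depth and speed.

    The trochanter advances at exactly ``speed`` on average and the ankle
    repeats a stance/swing template with stride length chosen by the
    speed-stride relation, so stride detection has an exact ground truth.
    ``depth`` does not alter the waveform (the template is a kinematic
    study condition, not a fluid simulation); it is accepted so trials
    carry their condition.  Gaussian noise of ``config.marker_noise_sd``
    is added to every coordinate.  ``stride_length`` overrides the
    speed-stride relation (useful to time-scale a fixed waveform).
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    rng = np.random.default_rng(seed)
    h = participant.stature
    sl = stride_length if stride_length is not None else stride_length_for_speed(speed, h)
    duration = sl / speed
    if n_strides is None:
        n_strides = max(6, config.strides_per_condition + 3)

    thigh = participant.segments["thigh"].length
    shank = participant.segments["shank"].length
    foot_len = participant.segments["foot"].length
    l_eff = KNEE_SLACK * (thigh + shank)
    if sl / 4.0 >= l_eff:
        raise ValueError(
            f"unreachable stride length {sl:.2f} m for leg strut {l_eff:.2f} m"
        )

    fs = config.sampling_rate
    total_t = (n_strides + 1.5) * duration
    t = np.arange(int(round(total_t * fs))) / fs

    # right heel strikes when the hip trails the new stance ankle by c;
    # right stance ankles sit at x = (m + 1) * sl
    c = DUTY_FACTOR * sl / 2.0
    t_strikes = (np.arange(n_strides + 1) * sl + sl - c) / speed
    hip_x = speed * t
    # hip rides on the nearest stance strut (ankles at k*sl/2)
    dx = np.mod(hip_x + sl / 4.0, sl / 2.0) - sl / 4.0
    hip_y = ANKLE_HEIGHT + np.sqrt(l_eff**2 - dx**2)

    ank_x, ank_y = _ankle_trajectory(t, t_strikes, sl, duration, DUTY_FACTOR)
    ank_x = ank_x + sl  # stance grid offset so strikes line up with hip_x

    # two-link inverse kinematics for the knee, forward-flexed solution
    ux = ank_x - hip_x
    uy = ank_y - hip_y
    d = np.hypot(ux, uy)
    d = np.clip(d, abs(thigh - shank) + 1e-6, 0.999 * (thigh + shank))
    ux, uy = ux / d, uy / d
    cos_a = (thigh**2 + d**2 - shank**2) / (2.0 * thigh * d)
    cos_a = np.clip(cos_a, -1.0, 1.0)
    sin_a = np.sqrt(1.0 - cos_a**2)
    knee_x = hip_x + thigh * (cos_a * ux - sin_a * uy)
    knee_y = hip_y + thigh * (cos_a * uy + sin_a * ux)

    trunk_len = participant.segments["trunk"].length
    markers = {
        "greater_trochanter": (hip_x, hip_y),
        "femoral_epicondyle": (knee_x, knee_y),
        "lateral_malleolus": (ank_x, ank_y),
        "calcaneus": (ank_x - 0.04, ank_y - ANKLE_HEIGHT),
        "fifth_metatarsal": (ank_x + foot_len - 0.04, ank_y - ANKLE_HEIGHT + 0.01),
        "umbilicus": (hip_x + 0.01, hip_y + 0.5 * trunk_len),
        "xiphoid": (hip_x + 0.02, hip_y + trunk_len),
    }
    data = {}
    for lm in LANDMARKS:
        x, y = markers[lm]
        data[f"{lm}_x"] = x + rng.normal(0.0, config.marker_noise_sd, size=len(t))
        data[f"{lm}_y"] = y + rng.normal(0.0, config.marker_noise_sd, size=len(t))
    return MarkerTrajectorySet(
        sampling_rate=fs, time=t, data=pd.DataFrame(data)
    )


def generate_metabolic_data(
    true_cot: float,
    speed: float,
    mass: float,
    config: CohortConfig,
    seed: int,
):
    """Breath-by-breath walking and resting gas exchange encoding a known
    net cost of transport.

    The walking net power is ``true_cot * speed * 60`` J/kg/min on top of a
    standing baseline; both are inverted through the RER-dependent energy
    equivalent at a trial RER drawn from the study band, so a noise-free
    record decodes back to ``true_cot`` exactly.  Per-breath multiplicative
    lognormal noise with coefficient of variation
    ``config.metabolic_noise_cv`` is applied to both gases coherently.
    Returns ``(walk_record, rest_record, rer)``.
    """
    if true_cot <= 0 or speed <= 0 or mass <= 0:
        raise ValueError("true_cot, speed and mass must be positive")
    rng = np.random.default_rng(seed)
    rer = float(rng.uniform(*config.rer_band))
    e_o2 = energy_equivalent_garby_astrup(rer)  # J/ml O2

    net_power = true_cot * speed * 60.0  # J/kg/min
    gross_walk = net_power + REST_GROSS_POWER
    records = []
    for gross, duration in (
        (gross_walk, config.walk_duration),
        (REST_GROSS_POWER, config.rest_duration),
    ):
        n = int(duration / config.breath_interval)
        times = np.cumsum(
            rng.uniform(0.8 * config.breath_interval, 1.2 * config.breath_interval, n)
        )
        vo2 = gross * mass / e_o2  # ml/min
        cv = config.metabolic_noise_cv
        if cv > 0:
            sigma = np.sqrt(np.log(1.0 + cv**2))
            noise = rng.lognormal(-0.5 * sigma**2, sigma, size=n)  # unit mean
        else:
            noise = np.ones(n)
        vo2_series = vo2 * noise
        records.append(
            CalorimetryRecord(time=times, vo2=vo2_series, vco2=rer * vo2_series)
        )
    return records[0], records[1], rer
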