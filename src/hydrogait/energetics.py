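"""Per-stride mechanical work, predicted cost of transport, and indirect
calorimetry.

The mechanical model splits the external work of an immersed stride into a
horizontal part done against drag, ``W_D = DrF * SL``, and a vertical part
done lifting the centre of mass against the apparent (buoyancy-reduced)
weight.  The vertical excursion per contact phase follows the compass-gait
approximation ``COM_vert = L_leg * (1 - cos(0.5 * L_sc / L_leg))`` and is
paid twice per stride, so ``W_v = GRF_v * 2 * COM_vert``.  The predicted
cost of transport converts total work to metabolic cost through an assumed
muscle efficiency of 0.25 (concentric actions dominate in water):

    COT_predicted = (W_D + W_v) / (SL * mass * efficiency)   [J/kg/m]

Measured cost comes from breath-by-breath gas exchange: gross metabolic
power from an energy-equivalent-of-oxygen equation, net power by
subtracting the at-rest gross power at the same immersion depth, and COT by
dividing net power by speed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnergeticsResult",
    "CalorimetryRecord",
    "MeasuredCost",
    "horizontal_work",
    "com_vertical_displacement",
    "vertical_work",
    "total_work",
    "cot_predicted",
    "stride_energetics",
    "energy_equivalent_garby_astrup",
    "metabolic_power",
    "measured_cot",
    "read_gas_exchange",
]

DEFAULT_EFFICIENCY = 0.25
#: Default analysis window: the final 2 min of a 5-min trial.
DEFAULT_WINDOW_SECONDS = 120.0
RER_SANITY_BAND = (0.6, 1.3)


@dataclass(frozen=True)
class EnergeticsResult:
    """Mechanical work terms and predicted cost for one stride."""

    horizontal_work: float  # W_D, J
    com_vertical: float  # m
    vertical_work: float  # W_v, J
    total_work: float  # W_Aqua, J
    cot_predicted: float  # J/kg/m
    efficiency: float

    def __post_init__(self) -> None:
        if abs(self.total_work - (self.horizontal_work + self.vertical_work)) > 1e-9:
            raise ValueError("W_Aqua must equal W_D + W_v")
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must lie in (0, 1]")


def horizontal_work(drf: float, stride_length: float) -> float:
    """Work against drag over one stride: ``W_D = DrF * SL`` (J)."""
    if drf < 0:
        raise ValueError("DrF must be non-negative")
    if stride_length <= 0:
        raise ValueError("stride_length must be positive")
    return drf * stride_length


def com_vertical_displacement(leg_length: float, l_sc: float) -> float:
    """Compass-gait vertical excursion of the COM per contact phase (m).

    ``L_leg * (1 - cos(0.5 * L_sc / L_leg))`` — the stance leg pivots as a
    strut, so the hip rises on an arc of radius ``L_leg`` while advancing
    ``L_sc`` during single support.
    """
    if leg_length <= 0:
        raise ValueError("leg_length must be positive")
    if l_sc < 0:
        raise ValueError("L_sc must be non-negative")
    if l_sc / leg_length >= math.pi:
        raise ValueError("L_sc exceeds the half-circle arc of the stance leg")
    return leg_length * (1.0 - math.cos(0.5 * l_sc / leg_length))


def vertical_work(grf_v: float, com_vertical: float) -> float:
    """Work lifting the COM against the apparent weight, both contact
    phases of a stride: ``W_v = GRF_v * 2 * COM_vert`` (J)."""
    if grf_v < 0 or com_vertical < 0:
        raise ValueError("GRF_v and COM_vert must be non-negative")
    return grf_v * com_vertical * 2.0


def total_work(w_d: float, w_v: float) -> float:
    """Total external mechanical work per stride: ``W_Aqua = W_D + W_v`` (J)."""
    return w_d + w_v


def cot_predicted(
    w_aqua: float,
    stride_length: float,
    mass: float,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> float:
    """Predicted cost of transport (J/kg/m)."""
    if stride_length <= 0 or mass <= 0:
        raise ValueError("stride_length and mass must be positive")
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must lie in (0, 1]")
    return w_aqua / (stride_length * mass * efficiency)


def stride_energetics(
    drf: float,
    stride_length: float,
    leg_length: float,
    l_sc: float,
    grf_v: float,
    mass: float,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> EnergeticsResult:
    """Convenience wrapper running the whole per-stride work chain."""
    w_d = horizontal_work(drf, stride_length)
    com = com_vertical_displacement(leg_length, l_sc)
    w_v = vertical_work(grf_v, com)
    w_aqua = total_work(w_d, w_v)
    return EnergeticsResult(
        horizontal_work=w_d,
        com_vertical=com,
        vertical_work=w_v,
        total_work=w_aqua,
        cot_predicted=cot_predicted(w_aqua, stride_length, mass, efficiency),
        efficiency=efficiency,
    )


@dataclass(frozen=True)
class CalorimetryRecord:
    """Breath-by-breath gas exchange series."""

    time: np.ndarray  # s
    vo2: np.ndarray  # ml/min
    vco2: np.ndarray  # ml/min

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.vo2) == len(self.vco2)):
            raise ValueError("time, VO2 and VCO2 must have equal length")

    @property
    def rer(self) -> np.ndarray:
        return self.vco2 / self.vo2

    def window(self, t_start: float, t_stop: float) -> "CalorimetryRecord":
        m = (self.time >= t_start) & (self.time <= t_stop)
        return CalorimetryRecord(self.time[m], self.vo2[m], self.vco2[m])

    def final_window(self, seconds: float = DEFAULT_WINDOW_SECONDS) -> "CalorimetryRecord":
        if len(self.time) == 0:
            raise ValueError("empty gas-exchange record")
        t_end = float(self.time[-1])
        return self.window(t_end - seconds, t_end)


@dataclass(frozen=True)
class MeasuredCost:
    """Indirect-calorimetry cost summary for one condition."""

    gross_power_walk: float  # J/kg/min
    gross_power_rest: float  # J/kg/min
    net_power: float  # J/kg/min
    cot: float  # J/kg/m
    speed: float  # m/s


def energy_equivalent_garby_astrup(rer: float) -> float:
    """Energy equivalent of oxygen, J per ml O2, as a linear function of
    the respiratory exchange ratio: ``16.04 + 4.94 * RER``."""
    return 16.04 + 4.94 * rer


def _energy_rate_brockway(vo2_ml_min: float, vco2_ml_min: float) -> float:
    # J/min from ml/min of each gas (protein oxidation neglected)
    return 16.58 * vo2_ml_min + 4.51 * vco2_ml_min


def metabolic_power(
    record: CalorimetryRecord,
    mass: float,
    equation: str = "garby_astrup",
) -> float:
    """Gross metabolic power (J/kg/min) from a gas-exchange window.

    ``equation`` selects the energy-equivalent formulation:
    ``"garby_astrup"`` (RER-dependent J/ml O2) or ``"brockway"`` (linear in
    VO2 and VCO2).  Warns when the window RER leaves the physiological
    sanity band or exceeds 1.0 (aerobic-only assumption violated).
    """
    if len(record.time) == 0:
        raise ValueError("empty gas-exchange window")
    if mass <= 0:
        raise ValueError("mass must be positive")
    vo2 = float(np.mean(record.vo2))
    vco2 = float(np.mean(record.vco2))
    if vo2 < 0:
        raise ValueError("mean VO2 must be non-negative")
    if vo2 == 0:
        return 0.0
    rer = vco2 / vo2
    if not RER_SANITY_BAND[0] < rer < RER_SANITY_BAND[1]:
        warnings.warn(
            f"window RER {rer:.2f} outside sanity band {RER_SANITY_BAND}",
            stacklevel=2,
        )
    elif rer > 1.0:
        warnings.warn(
            f"window RER {rer:.2f} > 1.0: aerobic-only assumption questionable",
            stacklevel=2,
        )
    if equation == "garby_astrup":
        joules_per_min = vo2 * energy_equivalent_garby_astrup(rer)
    elif equation == "brockway":
        joules_per_min = _energy_rate_brockway(vo2, vco2)
    else:
        raise ValueError(f"unknown calorimetry equation {equation!r}")
    return joules_per_min / mass


def measured_cot(
    gross_power_walk: float, gross_power_rest: float, speed: float
) -> MeasuredCost:
    """Net metabolic cost of transport from gross walking and resting power.

    ``COT = (gross_walk - gross_rest) / (60 * speed)`` in J/kg/m.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    if gross_power_walk < gross_power_rest:
        warnings.warn(
            "walking gross power below resting gross power; negative net cost",
            stacklevel=2,
        )
    net = gross_power_walk - gross_power_rest
    return MeasuredCost(
        gross_power_walk=gross_power_walk,
        gross_power_rest=gross_power_rest,
        net_power=net,
        cot=net / (60.0 * speed),
        speed=speed,
    )


def read_gas_exchange(path) -> CalorimetryRecord:
    """Read a gas-exchange CSV with columns time_s, VO2_ml_min, VCO2_ml_min."""
    df = pd.read_csv(path)
    required = ["time_s", "VO2_ml_min", "VCO2_ml_min"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"gas-exchange file missing columns: {missing}")
    return CalorimetryRecord(
        time=df["time_s"].to_numpy(dtype=float),
        vo2=df["VO2_ml_min"].to_numpy(dtype=float),
        vco2=df["VCO2_ml_min"].to_numpy(dtype=float),
    )
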