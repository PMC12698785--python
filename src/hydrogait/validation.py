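"""Model validation battery: agreement, cross-validation, bootstrap,
correlation, and one-at-a-time sensitivity.

The predicted cost of transport is a per-participant mechanical estimate;
its agreement with the measured cost is summarized by per-depth ratios of
condition means and an overall R^2 (fraction of measured-cost variance
explained when the prediction is used as the estimator).  Generalization
is probed by leave-one-participant-out cross-validation of a linear
calibration, stability by a participant-level bootstrap of R^2, and the
mechanical model's robustness by +/-10% one-at-a-time parameter
perturbations with analytic propagation rules (drag rescales with the
square of a speed change).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .energetics import stride_energetics

__all__ = [
    "ValidationReport",
    "SensitivityResult",
    "EnergeticsInputs",
    "prediction_agreement",
    "loocv_r2",
    "bootstrap_r2_ci",
    "sensitivity",
    "sensitivity_table",
    "correlations",
]

SENSITIVITY_PARAMETERS = (
    "muscle_efficiency",
    "body_mass",
    "walking_speed",
    "stride_length",
)


def _identity_r2(pred: np.ndarray, meas: np.ndarray) -> float:
    """R^2 of the prediction used directly as the estimator of the
    measurement: ``1 - SS_res / SS_tot``."""
    ss_res = float(np.sum((meas - pred) ** 2))
    ss_tot = float(np.sum((meas - meas.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-12 else -np.inf
    return 1.0 - ss_res / ss_tot


def prediction_agreement(pred, meas, groups=None):
    """Per-group mean ratios and overall R^2 of predicted vs measured cost.

    The group ratio is ``mean(pred) / mean(meas)`` within the group (e.g.
    one immersion depth pooled across speeds).  Returns ``(ratios, r2)``
    with ratios an ordered dict group -> ratio.
    """
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.shape != meas.shape:
        raise ValueError("pred and meas must have the same length")
    if np.any(meas == 0):
        raise ValueError("measured values must be non-zero")
    ratios = {}
    if groups is not None:
        groups = np.asarray(groups)
        if groups.shape != pred.shape:
            raise ValueError("groups must match data length")
        for g in dict.fromkeys(groups.tolist()):  # preserve first-seen order
            m = groups == g
            ratios[g] = float(pred[m].mean() / meas[m].mean())
    return ratios, _identity_r2(pred, meas)


def loocv_r2(pred, meas, units):
    """Leave-one-unit-out cross-validated R^2 of a linear calibration.

    For each unit (participant) a straight line measured ~ predicted is
    fit on the remaining units and evaluated on the held-out unit; the
    pooled out-of-sample predictions give ``1 - SS_res / SS_tot``.  When
    the prediction already equals the measurement the calibration is the
    identity and the cross-validated R^2 is 1; for a signal-free response
    it is non-positive in expectation.
    """
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    units = np.asarray(units)
    unique = np.unique(units)
    if len(unique) < 3:
        raise ValueError("LOOCV needs at least 3 units")
    out = np.empty_like(meas)
    for u in unique:
        test = units == u
        train = ~test
        slope, intercept = np.polyfit(pred[train], meas[train], 1)
        out[test] = slope * pred[test] + intercept
    return _identity_r2(out, meas)


def bootstrap_r2_ci(pred, meas, units, n_iter: int = 1000, seed: int = 0):
    """Participant-level bootstrap of the predicted-vs-measured R^2.

    Units are resampled with replacement ``n_iter`` times; all rows of a
    drawn unit enter together (within-participant dependence respected).
    Returns ``(mean, (lo, hi))`` with a 2.5/97.5 percentile interval.
    Deterministic for a fixed seed.
    """
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    units = np.asarray(units)
    if len(pred) == 0:
        raise ValueError("empty dataset")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    unique = np.unique(units)
    rows_by_unit = [np.flatnonzero(units == u) for u in unique]
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(unique), size=(n_iter, len(unique)))
    stats_out = np.empty(n_iter)
    for i in range(n_iter):
        idx = np.concatenate([rows_by_unit[j] for j in draws[i]])
        stats_out[i] = _identity_r2(pred[idx], meas[idx])
    finite = stats_out[np.isfinite(stats_out)]
    lo, hi = np.percentile(finite, [2.5, 97.5])
    return float(finite.mean()), (float(lo), float(hi))


@dataclass(frozen=True)
class EnergeticsInputs:
    """Baseline state of the mechanical model for sensitivity analysis."""

    drf: float  # N
    stride_length: float  # m
    l_sc: float  # m, forward displacement during single support
    leg_length: float  # m
    grf_v: float  # N
    mass: float  # kg
    speed: float  # m/s
    efficiency: float = 0.25

    def cot(self) -> float:
        return stride_energetics(
            self.drf,
            self.stride_length,
            self.leg_length,
            self.l_sc,
            self.grf_v,
            self.mass,
            self.efficiency,
        ).cot_predicted


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    pct_change_plus: float  # % change of COT_predicted at +10%
    pct_change_minus: float  # % at -10%
    mean_abs_pct: float


def _perturbed_cot(
    base: EnergeticsInputs, parameter: str, factor: float, mass_mode: str
) -> float:
    if parameter == "muscle_efficiency":
        return EnergeticsInputs(
            base.drf, base.stride_length, base.l_sc, base.leg_length,
            base.grf_v, base.mass, base.speed, base.efficiency * factor,
        ).cot()
    if parameter == "body_mass":
        grf = base.grf_v * factor if mass_mode == "propagate" else base.grf_v
        return EnergeticsInputs(
            base.drf, base.stride_length, base.l_sc, base.leg_length,
            grf, base.mass * factor, base.speed, base.efficiency,
        ).cot()
    if parameter == "walking_speed":
        # pressure drag is quadratic in velocity
        return EnergeticsInputs(
            base.drf * factor**2, base.stride_length, base.l_sc, base.leg_length,
            base.grf_v, base.mass, base.speed * factor, base.efficiency,
        ).cot()
    if parameter == "stride_length":
        # L_sc scales with SL; W_D = DrF*SL and the denominator both scale
        return EnergeticsInputs(
            base.drf, base.stride_length * factor, base.l_sc * factor,
            base.leg_length, base.grf_v, base.mass, base.speed, base.efficiency,
        ).cot()
    raise ValueError(f"unknown sensitivity parameter {parameter!r}")


def sensitivity(
    baseline: EnergeticsInputs,
    parameter: str,
    delta: float = 0.10,
    mass_mode: str = "denominator_only",
) -> SensitivityResult:
    """Percent change of the predicted cost under a +/-``delta`` change
    of one input parameter.

    ``mass_mode`` controls whether a mass change also rescales the
    apparent weight (``"propagate"``) or only the normalizing denominator
    (``"denominator_only"``, the default — the proportional-inverse
    response is exact under that convention).
    """
    if mass_mode not in ("denominator_only", "propagate"):
        raise ValueError(f"unknown mass_mode {mass_mode!r}")
    base_cot = baseline.cot()
    if base_cot <= 0:
        raise ValueError("baseline COT_predicted must be positive")
    plus = _perturbed_cot(baseline, parameter, 1.0 + delta, mass_mode)
    minus = _perturbed_cot(baseline, parameter, 1.0 - delta, mass_mode)
    pct_plus = 100.0 * (plus - base_cot) / base_cot
    pct_minus = 100.0 * (minus - base_cot) / base_cot
    return SensitivityResult(
        parameter=parameter,
        pct_change_plus=pct_plus,
        pct_change_minus=pct_minus,
        mean_abs_pct=(abs(pct_plus) + abs(pct_minus)) / 2.0,
    )


def sensitivity_table(
    baseline: EnergeticsInputs, delta: float = 0.10, mass_mode="denominator_only"
) -> list[SensitivityResult]:
    return [
        sensitivity(baseline, p, delta, mass_mode) for p in SENSITIVITY_PARAMETERS
    ]


def correlations(cot, drf, grf_v):
    """Pearson correlations of measured cost with drag and vertical load.

    Returns ``{"cot_drf": (r, p), "cot_grf": (r, p)}``.
    """
    cot = np.asarray(cot, dtype=float)
    drf = np.asarray(drf, dtype=float)
    grf = np.asarray(grf_v, dtype=float)
    if len(cot) < 3:
        raise ValueError("need at least 3 observations")
    for name, v in (("cot", cot), ("drf", drf), ("grf_v", grf)):
        if np.allclose(v, v[0]):
            raise ValueError(f"{name} has zero variance")
    r1 = stats.pearsonr(cot, drf)
    r2 = stats.pearsonr(cot, grf)
    return {
        "cot_drf": (float(r1.statistic), float(r1.pvalue)),
        "cot_grf": (float(r2.statistic), float(r2.pvalue)),
    }


@dataclass
class ValidationReport:
    """Aggregated validation results, serializable to JSON and text."""

    ratios_per_depth: dict
    overall_r2: float
    loocv_r2: float
    bootstrap_r2_mean: float
    bootstrap_r2_ci: tuple
    pearson_cot_drf: tuple
    pearson_cot_grf: tuple
    sensitivity: list = field(default_factory=list)
    seed: int | None = None

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["sensitivity"] = [asdict(s) for s in self.sensitivity]
        Path(path).write_text(json.dumps(payload, indent=2, default=float))

    def to_text(self) -> str:
        lines = [
            "Validation report",
            "=================",
            f"random seed: {self.seed}",
            "predicted/measured mean ratio per depth: "
            + ", ".join(f"{k}: {v:.2f}" for k, v in self.ratios_per_depth.items()),
            f"overall R^2 (pred vs meas): {self.overall_r2:.3f}",
            f"LOOCV R^2: {self.loocv_r2:.3f}",
            f"bootstrap R^2: {self.bootstrap_r2_mean:.3f} "
            f"[95% CI {self.bootstrap_r2_ci[0]:.3f}, {self.bootstrap_r2_ci[1]:.3f}]",
            f"Pearson r (COT, DrF): {self.pearson_cot_drf[0]:.3f} "
            f"(p={self.pearson_cot_drf[1]:.2g})",
            f"Pearson r (COT, GRF_v): {self.pearson_cot_grf[0]:.3f} "
            f"(p={self.pearson_cot_grf[1]:.2g})",
            "sensitivity (+10% / -10% / mean |change|):",
        ]
        for s in self.sensitivity:
            lines.append(
                f"  {s.parameter}: {s.pct_change_plus:+.1f}% / "
                f"{s.pct_change_minus:+.1f}% / {s.mean_abs_pct:.1f}%"
            )
        return "\n".join(lines)
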