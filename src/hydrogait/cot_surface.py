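"""Quadratic cost-of-transport response surface and comparative curves.

COT is modelled as a full second-degree polynomial in walking speed s and
immersion depth d,

    COT(s, d) = a_ss s^2 + a_dd d^2 + a_sd s d + a_s s + a_d d + a_0,

fit by ordinary least squares to per-condition costs.  The module also
fits per-depth COT(speed) quadratics and classifies their shape (an
interior minimum marks the U/J-shaped relation familiar from dry-land
walking), locates surface extrema over a bounded box, finds iso-cost
speeds against user-supplied reference curves (swimming, dry-land
walking), and evaluates self-selected-speed summaries with unit
conversions to W/kg, ml O2/kg/min, cal/kg/min and MET.

Reference curves are configuration: coefficient sets with a declared
validity range.  Evaluating outside that range warns (several published
curves are extrapolations at walking speeds) but does not fail.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm

from .energetics import energy_equivalent_garby_astrup

__all__ = [
    "SurfaceModel",
    "ReferenceCOTCurve",
    "QuadraticSpeedCurve",
    "SelfSelectedSummary",
    "fit_surface",
    "evaluate_surface",
    "surface_extrema",
    "per_depth_curve",
    "iso_cost_speed",
    "self_selected_summary",
    "load_reference_curves",
]

TERM_NAMES = ("speed2", "depth2", "speed_depth", "speed", "depth", "intercept")

JOULES_PER_CALORIE = 4.186
MLO2_PER_KG_MIN_PER_MET = 3.5


def _design(speed: np.ndarray, depth: np.ndarray) -> np.ndarray:
    s = np.asarray(speed, dtype=float)
    d = np.asarray(depth, dtype=float)
    return np.column_stack([s * s, d * d, s * d, s, d, np.ones_like(s)])


@dataclass(frozen=True)
class SurfaceModel:
    """Fitted (or externally supplied) quadratic COT surface."""

    coefficients: tuple  # ordered as TERM_NAMES
    r_squared: float | None = None
    conf_int: dict | None = None  # term -> (lo, hi)
    speed_domain: tuple = (0.2, 0.8)
    depth_domain: tuple = (0.5, 1.3)

    def __post_init__(self) -> None:
        if len(self.coefficients) != 6:
            raise ValueError("surface needs exactly 6 coefficients")
        if self.r_squared is not None and self.r_squared > 1:
            raise ValueError("R^2 cannot exceed 1")

    def evaluate(self, speed, depth):
        s = np.asarray(speed, dtype=float)
        d = np.asarray(depth, dtype=float)
        a_ss, a_dd, a_sd, a_s, a_d, a0 = self.coefficients
        return a_ss * s * s + a_dd * d * d + a_sd * s * d + a_s * s + a_d * d + a0

    def to_json(self, path) -> None:
        payload = {
            "coefficients": dict(zip(TERM_NAMES, map(float, self.coefficients))),
            "r_squared": self.r_squared,
            "conf_int": self.conf_int,
            "speed_domain": list(self.speed_domain),
            "depth_domain": list(self.depth_domain),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "SurfaceModel":
        payload = json.loads(Path(path).read_text())
        coefs = tuple(payload["coefficients"][t] for t in TERM_NAMES)
        return cls(
            coefficients=coefs,
            r_squared=payload.get("r_squared"),
            conf_int=payload.get("conf_int"),
            speed_domain=tuple(payload.get("speed_domain", (0.2, 0.8))),
            depth_domain=tuple(payload.get("depth_domain", (0.5, 1.3))),
        )


def fit_surface(speed, depth, cot) -> SurfaceModel:
    """Ordinary least squares on the six-term quadratic design.

    Needs at least six points spanning the design (rank 6); returns the
    fitted model with in-sample R^2 and 95% coefficient confidence
    intervals from the OLS covariance matrix.
    """
    s = np.asarray(speed, dtype=float)
    d = np.asarray(depth, dtype=float)
    y = np.asarray(cot, dtype=float)
    if not (len(s) == len(d) == len(y)):
        raise ValueError("speed, depth and cot must have equal length")
    if len(y) < 6:
        raise ValueError("need at least 6 points to fit the quadratic surface")
    X = _design(s, d)
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError("rank-deficient design: points are collinear/degenerate")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    return SurfaceModel(
        coefficients=tuple(float(b) for b in res.params),
        r_squared=float(res.rsquared),
        conf_int={
            t: (float(lo), float(hi)) for t, (lo, hi) in zip(TERM_NAMES, np.asarray(ci))
        },
        speed_domain=(float(s.min()), float(s.max())),
        depth_domain=(float(d.min()), float(d.max())),
    )


def evaluate_surface(model: SurfaceModel, speed, depth, allow_extrapolation=False):
    """Evaluate the surface; warn (or raise) outside the fit domain."""
    s = np.asarray(speed, dtype=float)
    d = np.asarray(depth, dtype=float)
    out = (
        (s < model.speed_domain[0] - 1e-9)
        | (s > model.speed_domain[1] + 1e-9)
        | (d < model.depth_domain[0] - 1e-9)
        | (d > model.depth_domain[1] + 1e-9)
    )
    if np.any(out):
        msg = (
            f"evaluating surface outside fit domain speed={model.speed_domain}, "
            f"depth={model.depth_domain}"
        )
        if allow_extrapolation:
            warnings.warn(msg, stacklevel=2)
        else:
            warnings.warn(msg + " (extrapolated values are unvalidated)", stacklevel=2)
    return model.evaluate(s, d)


def surface_extrema(model: SurfaceModel, speed_bounds, depth_bounds):
    """Global min and max of the surface over a bounded box.

    Candidates are the interior critical point (when the Hessian is
    non-singular and the point falls inside the box), the vertices of the
    1-D quadratics along each edge, and the four corners.  Returns
    ``(minimum, maximum)`` dicts with value, location and whether the
    extremum is interior or on the boundary.
    """
    s_lo, s_hi = map(float, speed_bounds)
    d_lo, d_hi = map(float, depth_bounds)
    if not (s_lo < s_hi and d_lo < d_hi):
        raise ValueError("degenerate bounds")
    a_ss, a_dd, a_sd, a_s, a_d, _ = model.coefficients

    candidates: list[tuple[float, float, str]] = []
    # interior critical point: grad = 0
    H = np.array([[2 * a_ss, a_sd], [a_sd, 2 * a_dd]])
    if abs(np.linalg.det(H)) > 1e-12:
        s_c, d_c = np.linalg.solve(H, [-a_s, -a_d])
        if s_lo < s_c < s_hi and d_lo < d_c < d_hi:
            candidates.append((float(s_c), float(d_c), "interior"))
    # edge vertices: 1-D quadratic along each edge
    for d_edge in (d_lo, d_hi):
        if abs(a_ss) > 1e-12:
            s_v = -(a_sd * d_edge + a_s) / (2 * a_ss)
            if s_lo < s_v < s_hi:
                candidates.append((float(s_v), d_edge, "boundary"))
    for s_edge in (s_lo, s_hi):
        if abs(a_dd) > 1e-12:
            d_v = -(a_sd * s_edge + a_d) / (2 * a_dd)
            if d_lo < d_v < d_hi:
                candidates.append((s_edge, float(d_v), "boundary"))
    for s_c in (s_lo, s_hi):
        for d_c in (d_lo, d_hi):
            candidates.append((s_c, d_c, "boundary"))

    evaluated = [
        {"value": float(model.evaluate(s, d)), "speed": s, "depth": d, "where": w}
        for s, d, w in candidates
    ]
    minimum = min(evaluated, key=lambda e: e["value"])
    maximum = max(evaluated, key=lambda e: e["value"])
    return minimum, maximum


@dataclass(frozen=True)
class QuadraticSpeedCurve:
    """COT as a quadratic in speed at one immersion depth."""

    depth: float
    coefficients: tuple  # (c2, c1, c0), highest power first
    speed_range: tuple
    shape: str  # "interior_minimum" | "interior_maximum" | "monotone"
    vertex_speed: float | None

    def evaluate(self, speed):
        return np.polyval(self.coefficients, np.asarray(speed, dtype=float))


def per_depth_curve(speeds, cots, depth: float = float("nan")) -> QuadraticSpeedCurve:
    """Quadratic COT(speed) fit at a single depth, with shape classification.

    The curve is classified ``interior_minimum`` (J/U-shaped) only when its
    curvature is positive and the vertex lies strictly inside the tested
    speed range.
    """
    s = np.asarray(speeds, dtype=float)
    y = np.asarray(cots, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 speeds for a quadratic fit")
    c2, c1, c0 = np.polyfit(s, y, 2)
    lo, hi = float(s.min()), float(s.max())
    vertex = -c1 / (2 * c2) if abs(c2) > 1e-12 else None
    if vertex is not None and lo < vertex < hi:
        shape = "interior_minimum" if c2 > 0 else "interior_maximum"
    else:
        shape = "monotone"
    return QuadraticSpeedCurve(
        depth=float(depth),
        coefficients=(float(c2), float(c1), float(c0)),
        speed_range=(lo, hi),
        shape=shape,
        vertex_speed=float(vertex) if vertex is not None else None,
    )


@dataclass(frozen=True)
class ReferenceCOTCurve:
    """Config-supplied COT(speed) curve of another locomotion mode.

    ``coefficients`` are polynomial coefficients, highest power first.
    ``speed_range`` is the validity range of the source equation;
    evaluation outside it warns about extrapolation.
    """

    name: str
    coefficients: tuple
    speed_range: tuple

    def evaluate(self, speed, warn: bool = True):
        s = np.asarray(speed, dtype=float)
        if warn and np.any((s < self.speed_range[0]) | (s > self.speed_range[1])):
            warnings.warn(
                f"reference curve {self.name!r} evaluated outside its validity "
                f"range {self.speed_range}: extrapolated",
                stacklevel=2,
            )
        return np.polyval(self.coefficients, s)


def load_reference_curves(path) -> dict[str, ReferenceCOTCurve]:
    """Load reference curves from a JSON config.

    Schema: ``{name: {"coefficients": [...], "speed_range": [lo, hi]}}``.
    Entries with null coefficients (template placeholders) are skipped.
    """
    payload = json.loads(Path(path).read_text())
    curves = {}
    for name, spec in payload.items():
        if spec.get("coefficients") is None:
            continue
        curves[name] = ReferenceCOTCurve(
            name=name,
            coefficients=tuple(float(c) for c in spec["coefficients"]),
            speed_range=tuple(spec.get("speed_range", (0.0, np.inf))),
        )
    return curves


def iso_cost_speed(curve_a, curve_b, speed_range, tol: float = 1e-9):
    """Speeds in ``speed_range`` where two COT curves intersect.

    For two polynomial curves the roots of the difference polynomial are
    found in closed form; identical curves are flagged degenerate; an
    empty list is a valid answer (one mode dominates everywhere).  Each
    returned root satisfies ``|A(s) - B(s)| < tol``.
    Returns ``(points, degenerate)`` with points a list of ``(speed, cot)``.
    """
    lo, hi = map(float, speed_range)
    ca = np.asarray(curve_a.coefficients, dtype=float)
    cb = np.asarray(curve_b.coefficients, dtype=float)
    n = max(len(ca), len(cb))
    diff = np.zeros(n)
    diff[n - len(ca):] += ca
    diff[n - len(cb):] -= cb
    if np.allclose(diff, 0.0, atol=tol):
        return [], True
    diff = np.trim_zeros(diff, "f")
    roots = np.roots(diff) if len(diff) > 1 else np.array([])
    points = []
    for r in roots:
        if abs(r.imag) > 1e-9:
            continue
        s = float(r.real)
        if lo - 1e-12 <= s <= hi + 1e-12:
            a_val = float(curve_a.evaluate(s, warn=False)) if isinstance(
                curve_a, ReferenceCOTCurve
            ) else float(curve_a.evaluate(s))
            b_val = float(curve_b.evaluate(s, warn=False)) if isinstance(
                curve_b, ReferenceCOTCurve
            ) else float(curve_b.evaluate(s))
            if abs(a_val - b_val) < max(tol, 1e-7 * max(abs(a_val), 1.0)):
                points.append((s, a_val))
    points.sort()
    return points, False


@dataclass(frozen=True)
class SelfSelectedSummary:
    """Predicted cost and power at one depth's self-selected speed."""

    depth: float  # m
    speed: float  # m/s
    cot: float  # J/kg/m
    power_w_per_kg: float  # W/kg = COT * speed
    vo2_ml_kg_min: float
    cal_kg_min: float
    met: float


def self_selected_summary(
    model: SurfaceModel,
    speeds_per_depth: dict,
    rer: float = 0.83,
) -> list[SelfSelectedSummary]:
    """Evaluate the surface at each depth's self-selected speed.

    Power is ``COT * speed`` (W/kg); oxygen uptake converts through the
    RER-dependent energy equivalent; 1 MET = 3.5 ml O2/kg/min.
    """
    rows = []
    e_o2 = energy_equivalent_garby_astrup(rer)  # J/ml O2
    for depth, speed in speeds_per_depth.items():
        if speed <= 0:
            raise ValueError("self-selected speed must be positive")
        d = float(depth)
        cot = float(evaluate_surface(model, speed, d))
        power = cot * speed  # W/kg
        j_kg_min = power * 60.0
        vo2 = j_kg_min / e_o2  # ml O2/kg/min
        rows.append(
            SelfSelectedSummary(
                depth=d,
                speed=float(speed),
                cot=cot,
                power_w_per_kg=power,
                vo2_ml_kg_min=vo2,
                cal_kg_min=j_kg_min / JOULES_PER_CALORIE,
                met=vo2 / MLO2_PER_KG_MIN_PER_MET,
            )
        )
    return rows
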