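"""End-to-end orchestration: synthetic cohort -> kinematics -> drag ->
energetics -> calorimetry -> surface fit -> comparisons -> validation.

Every stage consumes the previous stage's serialized products and mutates
nothing upstream; a run is idempotent for a fixed config and seed and
writes a provenance block (config hash, seed, package version) next to its
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, reference
from .body_model import build_segment_model
from .cot_surface import (
    SurfaceModel,
    fit_surface,
    iso_cost_speed,
    load_reference_curves,
    per_depth_curve,
    self_selected_summary,
    surface_extrema,
)
from .energetics import measured_cot, metabolic_power, stride_energetics
from .gait_kinematics import detect_strides, filter_markers, segment_states
from .hydrodynamics import WaterProperties, stride_drag
from .hydrostatics import WeightBearingTable, immersion_state
from .synthetic_cohort import CohortConfig, generate_cohort, generate_gait_trial, \
    generate_metabolic_data
from .validation import (
    EnergeticsInputs,
    ValidationReport,
    bootstrap_r2_ci,
    correlations,
    loocv_r2,
    prediction_agreement,
    sensitivity_table,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_full_analysis", "trial_seed"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full analysis run.

    ``reference_curves`` points to a JSON file of comparative COT(speed)
    polynomial curves (see :func:`hydrogait.cot_surface.load_reference_curves`);
    when absent the iso-cost stage is skipped with a warning.  Self-selected
    speeds map immersion depth (m) to speed (m/s).
    """

    output_dir: str = "hydrogait_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_strips: int = 20
    filter_cutoff: float = 4.5  # Hz
    calorimetry_equation: str = "garby_astrup"
    drag_aggregation: str = "time_average"
    include_foot: bool = True
    reference_curves: str | None = None
    self_selected_speeds: dict = field(
        default_factory=lambda: {
            reference.STUDY_DEPTHS[k]: v
            for k, v in reference.SELF_SELECTED_SPEEDS.items()
        }
    )
    bootstrap_iterations: int = 1000

    def __post_init__(self) -> None:
        if self.n_strips < 1:
            raise ValueError("n_strips must be >= 1")
        if self.filter_cutoff <= 0:
            raise ValueError("filter_cutoff must be positive")
        if self.calorimetry_equation not in ("garby_astrup", "brockway"):
            raise ValueError(f"unknown calorimetry equation {self.calorimetry_equation!r}")
        if self.bootstrap_iterations < 1:
            raise ValueError("bootstrap_iterations must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    results: pd.DataFrame  # one row per participant x condition
    surface: SurfaceModel
    extrema: tuple
    per_depth: dict
    self_selected: list
    isocost: pd.DataFrame | None
    report: ValidationReport
    output_dir: Path


def trial_seed(base_seed: int, *indices: int) -> int:
    """Deterministic per-trial child seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _analyze_trial(participant, depth, speed, config: RunConfig, seed: int):
    """Kinematics -> drag -> per-stride energetics for one synthetic trial."""
    cohort = config.cohort
    trial = generate_gait_trial(participant, depth, speed, cohort, seed)
    filtered = filter_markers(trial, config.filter_cutoff)
    strides = detect_strides(filtered)
    # keep the central analyzed strides, away from trial edges
    n_keep = cohort.strides_per_condition
    if len(strides) > n_keep:
        lo = max(1, (len(strides) - n_keep) // 2)
        strides = strides[lo:lo + n_keep]
    states = segment_states(filtered)
    frusta = build_segment_model(participant, include_foot=config.include_foot)
    water = WaterProperties(surface_height=depth)
    imm = immersion_state(depth, participant.stature, participant.mass)

    rows = []
    for stride in strides:
        drag = stride_drag(
            states,
            frusta,
            stride,
            water,
            dt=filtered.dt,
            n_strips=config.n_strips,
            aggregation=config.drag_aggregation,
        )
        energy = stride_energetics(
            drf=drag.drf,
            stride_length=stride.stride_length,
            leg_length=participant.leg_length,
            l_sc=stride.single_support_displacement,
            grf_v=imm.grf_vertical,
            mass=participant.mass,
            efficiency=cohort.efficiency,
        )
        rows.append(
            {
                "stride_length": stride.stride_length,
                "stride_speed": stride.speed,
                "l_sc": stride.single_support_displacement,
                "drf": drag.drf,
                "w_d": energy.horizontal_work,
                "w_v": energy.vertical_work,
                "w_aqua": energy.total_work,
                "cot_predicted": energy.cot_predicted,
            }
        )
    stride_df = pd.DataFrame(rows)
    summary = stride_df.mean().to_dict()
    summary["grf_v"] = imm.grf_vertical
    summary["weight_bearing"] = imm.weight_bearing_fraction
    summary["n_strides"] = len(stride_df)
    return summary, stride_df


def run_full_analysis(config: RunConfig) -> RunResult:
    """Execute every stage on a synthetic cohort and serialize the outputs.

    Products written to ``config.output_dir``: ``strides.csv`` (per stride),
    ``results.csv`` (per participant x condition), ``surface.json``,
    ``extrema.json``, ``per_depth_curves.json``, ``self_selected.csv``,
    ``isocost.csv`` (when reference curves are configured),
    ``validation.json``, ``report.txt`` and ``provenance.json``.
    """
    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = config.cohort

    participants, truth = generate_cohort(cohort)
    log.info("generated cohort of %d participants", len(participants))

    cond_rows = []
    stride_frames = []
    for i, participant in enumerate(participants):
        for j, depth in enumerate(cohort.depths):
            for k, speed in enumerate(cohort.speeds):
                seed_kin = trial_seed(cohort.seed, 1, i, j, k)
                summary, stride_df = _analyze_trial(
                    participant, depth, speed, config, seed_kin
                )
                t_row = truth[
                    (truth.participant_id == participant.participant_id)
                    & (truth.depth == depth)
                    & (truth.speed == speed)
                ].iloc[0]
                encoded_cot = (
                    float(summary["cot_predicted"])
                    if cohort.cot_source == "forward_model"
                    else float(t_row.true_cot)
                )
                walk, rest, rer = generate_metabolic_data(
                    encoded_cot,
                    speed,
                    participant.mass,
                    cohort,
                    trial_seed(cohort.seed, 2, i, j, k),
                )
                gross_walk = metabolic_power(
                    walk.final_window(), participant.mass, config.calorimetry_equation
                )
                gross_rest = metabolic_power(
                    rest.final_window(), participant.mass, config.calorimetry_equation
                )
                cost = measured_cot(gross_walk, gross_rest, speed)
                row = {
                    "participant_id": participant.participant_id,
                    "mass": participant.mass,
                    "stature": participant.stature,
                    "leg_length": participant.leg_length,
                    "depth": depth,
                    "speed": speed,
                    "rer": rer,
                    "cot_measured": cost.cot,
                    "true_cot": float(t_row.true_cot),
                    **summary,
                }
                cond_rows.append(row)
                stride_df.insert(0, "participant_id", participant.participant_id)
                stride_df.insert(1, "depth", depth)
                stride_df.insert(2, "speed", speed)
                stride_frames.append(stride_df)
        log.info("participant %s analyzed (%.1f s elapsed)",
                 participant.participant_id, time.time() - t_start)

    results = pd.DataFrame(cond_rows)
    pd.concat(stride_frames, ignore_index=True).to_csv(out / "strides.csv", index=False)
    results.to_csv(out / "results.csv", index=False)

    # response surface on per-condition mean measured cost, nominal speeds
    cond_means = (
        results.groupby(["depth", "speed"], as_index=False)["cot_measured"].mean()
    )
    surface = fit_surface(cond_means.speed, cond_means.depth, cond_means.cot_measured)
    surface.to_json(out / "surface.json")

    extrema = surface_extrema(
        surface,
        (min(cohort.speeds), max(cohort.speeds)),
        (min(cohort.depths), max(cohort.depths)),
    )
    (out / "extrema.json").write_text(
        json.dumps({"minimum": extrema[0], "maximum": extrema[1]}, indent=2)
    )

    per_depth = {}
    for depth, grp in cond_means.groupby("depth"):
        if len(grp) >= 3:
            per_depth[float(depth)] = per_depth_curve(
                grp.speed, grp.cot_measured, depth=float(depth)
            )
    (out / "per_depth_curves.json").write_text(
        json.dumps(
            {
                str(d): {
                    "coefficients": c.coefficients,
                    "shape": c.shape,
                    "vertex_speed": c.vertex_speed,
                }
                for d, c in per_depth.items()
            },
            indent=2,
        )
    )

    selfsel = self_selected_summary(surface, config.self_selected_speeds)
    pd.DataFrame([dataclasses.asdict(s) for s in selfsel]).to_csv(
        out / "self_selected.csv", index=False
    )

    isocost = None
    if config.reference_curves is not None:
        curves = load_reference_curves(config.reference_curves)
        if curves:
            iso_rows = []
            s_range = (min(cohort.speeds), max(cohort.speeds))
            for depth, sww_curve in per_depth.items():
                for name, ref_curve in curves.items():
                    points, degenerate = iso_cost_speed(sww_curve, ref_curve, s_range)
                    for s, cot_val in points:
                        iso_rows.append(
                            {"depth": depth, "reference": name,
                             "speed": s, "cot": cot_val}
                        )
            isocost = pd.DataFrame(iso_rows)
            isocost.to_csv(out / "isocost.csv", index=False)
        else:
            log.warning("reference-curve file has no filled entries; iso-cost skipped")
    else:
        log.warning("no reference curves configured; iso-cost stage skipped")

    # validation battery on participant x condition rows
    pred = results.cot_predicted.to_numpy()
    meas = results.cot_measured.to_numpy()
    units = results.participant_id.to_numpy()
    ratios, overall_r2 = prediction_agreement(pred, meas, groups=results.depth)
    cv_r2 = loocv_r2(pred, meas, units)
    boot_mean, boot_ci = bootstrap_r2_ci(
        pred, meas, units, n_iter=config.bootstrap_iterations,
        seed=trial_seed(cohort.seed, 3),
    )
    corr = correlations(meas, results.drf, results.grf_v)
    deepest = results[
        (results.depth == max(cohort.depths)) & (results.speed == max(cohort.speeds))
    ]
    baseline = EnergeticsInputs(
        drf=float(deepest.drf.mean()),
        stride_length=float(deepest.stride_length.mean()),
        l_sc=float(deepest.l_sc.mean()),
        leg_length=float(deepest.leg_length.mean()),
        grf_v=float(deepest.grf_v.mean()),
        mass=float(deepest.mass.mean()),
        speed=max(cohort.speeds),
        efficiency=cohort.efficiency,
    )
    report = ValidationReport(
        ratios_per_depth={str(k): v for k, v in ratios.items()},
        overall_r2=overall_r2,
        loocv_r2=cv_r2,
        bootstrap_r2_mean=boot_mean,
        bootstrap_r2_ci=boot_ci,
        pearson_cot_drf=corr["cot_drf"],
        pearson_cot_grf=corr["cot_grf"],
        sensitivity=sensitivity_table(baseline),
        seed=cohort.seed,
    )
    report.to_json(out / "validation.json")
    (out / "report.txt").write_text(report.to_text() + "\n")

    (out / "provenance.json").write_text(
        json.dumps(
            {
                "config_hash": config.config_hash(),
                "seed": cohort.seed,
                "version": __version__,
                "elapsed_s": round(time.time() - t_start, 2),
            },
            indent=2,
        )
    )
    log.info("run complete in %.1f s", time.time() - t_start)
    return RunResult(
        results=results,
        surface=surface,
        extrema=extrema,
        per_depth=per_depth,
        self_selected=selfsel,
        isocost=isocost,
        report=report,
        output_dir=out,
    )
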