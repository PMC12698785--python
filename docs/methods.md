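# Methods

This note documents the models implemented in `hydrogait`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real recordings.

## Body geometry

Foot, shank, thigh (bilateral) and trunk are conic frusta; radii come from
circumference measurements assuming circular cross-sections.  The trunk
frustum spans greater-trochanter to xiphoid level; head and arms are
excluded because they remain above the waterline at every immersion depth
considered (up to ~73 % of stature).  The foot is included as a frustum by
default and can be dropped (`include_foot=False`) — its drag contribution
is small because it moves slowly and sits near the floor.  Only geometry is
modelled; inertial parameters are not needed by any downstream stage.

Each frustum is split into `n_strips = 20` equal strips with the radius
evaluated at the strip midpoint.  Because the taper is linear, the midpoint
rule integrates any linear-in-radius quantity exactly at every strip count;
20 strips resolve the nonlinear parts (velocity and immersion profiles
along a segment) to well under 1 % (checked by doubling to 40).

## Kinematics

Marker trajectories (seven right-side sagittal landmarks, 60 Hz) are
low-pass filtered with a 2nd-order Butterworth applied forward and backward
(zero phase), default cutoff 4.5 Hz — the midpoint of the 4–5 Hz range
appropriate for slow gait.  Zero-phase filtering avoids timing bias in
event detection; it also commutes with differentiation on interior samples.
Gaps up to 3 samples are interpolated; longer gaps reject the trial.

Segment angles are measured from the vertical between the two bounding
landmarks; angular and linear velocities are central differences.  Foot
contact is declared when the calcaneus is below 0.02 m above the floor and
moving slower than 0.05 m/s horizontally; toe-off analogously on the fifth
metatarsal.  Contact runs or gaps shorter than 0.15 s are suppressed
(morphological closing/opening): with ~5 mm digitization noise the filtered
marker velocity fluctuates by ~0.06 m/s during stance, which would
otherwise fragment the contact mask.  All thresholds are arguments.
Strides run calcaneus contact to calcaneus contact; stride length is the
greater-trochanter displacement; `L_sc` is its displacement over the
longest single-support run, with the contralateral contact pattern
synthesized by a half-stride shift (only one body side carries markers).

## Drag

Pressure drag only, cross-flow principle: a strip's force is
½ ρ C_d A v_n |v_n| with A the diameter × strip length, prorated by the
immersed fraction so the waterline does not produce discretization jumps;
the axial velocity component generates no force.  Wave drag, skin friction
and added-mass (acceleration-reaction) forces are out of scope: at the
strip Reynolds numbers reached during immersed walking (10⁴–10⁶, reported
per stride) pressure drag dominates.  Defaults: ρ = 995.7 kg/m³ and
ν = 7.7·10⁻⁷ m²/s (thermoneutral pool water, 31–32 °C), C_d = 1.0 for both
limb and trunk classes (circular cylinder in cross-flow, turbulent regime),
all configurable per run.

The stride drag force DrF is the stride-time average of |Σ instantaneous
horizontal drag| over all segments (both legs plus trunk), computed
separately over the contact and swing windows and combined with duration
weights — algebraically the overall stride mean.  A time average (rather
than a time sum) is used so that DrF · SL is a work; an impulse-per-length
alternative (`aggregation="impulse_per_sl"`) is provided.  The
contralateral limb is the measured one with its force series shifted half a
stride, which assumes periodic, symmetric gait; the shift is applied to the
force series, not the positions, so no wrap discontinuity enters the
differentiation.

## Hydrostatics

The stride-mean vertical ground reaction force of steady walking equals the
supported weight; in water this is the apparent weight w·m·g.  The
weight-bearing fraction w is piecewise-linearly interpolated from a table
of (depth/stature, w) nodes — default (0, 1.00), (0.28, 0.88), (0.48,
0.58), (0.63, 0.48), (0.73, 0.33), calibrated so the four landmark depths
of a 1.78 m adult map to 0.88, 0.58, 0.48 and 0.33 g.  Beyond the last node
the final slope is continued (floored at 0.05).  w is also the
equivalent-gravity level, and the table inverse converts a gravity fraction
back to a depth, enabling comparison with simulated-hypogravity walking.
Buoyancy is reported as the complement, B = (1−w) m g, so B + GRF_v = m g
holds exactly.

## Energetics

Per stride: W_D = DrF·SL; COM_vert = L_leg (1 − cos(0.5 L_sc/L_leg))
(compass gait: the stance leg pivots as a rigid strut); W_v = GRF_v · 2 ·
COM_vert; W_Aqua = W_D + W_v; COT_predicted = W_Aqua/(SL · m · η) with
muscle efficiency η = 0.25 (concentric actions dominate under buoyancy).
Per-condition predictions are means over the analyzed strides (default 5).

Indirect calorimetry uses the final 2 minutes of a 5-minute trial.  The
default energy equivalent of oxygen is RER-dependent, E = 16.04 + 4.94·RER
J/ml O₂; a Brockway-style linear form in VO₂ and VCO₂ is the alternative
(the two differ by <1 % at RER 0.85).  A window RER above 1.0 (or outside
0.6–1.3) triggers a warning because the aerobic-only assumption breaks.
Net power subtracts the standing baseline at the same depth; COT = net
power / (60 · speed) in J/kg/m.

## Response surface and comparisons

Condition costs are fit by OLS on the six-term design (s², d², s·d, s, d,
1); coefficient CIs come from the OLS covariance.  Nominal target speeds
enter the fit by default (achieved speeds can be substituted).  Extrema
over a speed×depth box are found analytically: interior critical point,
edge-quadratic vertices and corners.  Per-depth quadratics are classified
"interior minimum" only when curvature is positive and the vertex lies
strictly inside the tested speed range.  Iso-cost speeds against reference
curves are closed-form polynomial roots verified by a residual check;
reference curves (swimming, dry-land walking, hypogravity surfaces) are
configuration — coefficient sets with declared validity ranges, shipped as
an empty template (`data/reference_curves_template.json`) because several
published equations are extrapolations at walking speeds; out-of-range
evaluation warns rather than fails.  Surface evaluation outside the fit
box also warns unless extrapolation is explicitly allowed.

## Validation battery

- Agreement: per-depth ratio mean(pred)/mean(meas) and overall
  R² = 1 − SS_res/SS_tot with the prediction used directly as estimator.
- LOOCV: a linear calibration measured~predicted refit with each
  participant held out; pooled out-of-sample R².  Equals 1 when predictions
  are exact; non-positive in expectation for signal-free responses.
- Bootstrap: participants resampled with replacement (rows of a drawn
  participant move together), 1 000 iterations, percentile 2.5/97.5 CI,
  deterministic per seed.
- Sensitivity: one-at-a-time ±10 % on efficiency, mass, speed and stride
  length.  Efficiency and mass act through the denominator only (mass
  optionally propagates to GRF_v), giving the exact inverse −9.1 %/+11.1 %.
  A speed change rescales DrF quadratically, giving +21 %/−19 % when drag
  dominates.  Stride length propagates into W_D, the COM excursion
  (L_sc ∝ SL) and the denominator; because W_D ∝ SL cancels against the
  denominator, the analytic response is near zero in drag-dominated
  conditions — a dampened response on real data is an empirical summary,
  not an identity.

## Synthetic cohort

The generator emulates the study conditions: nine adults (mass
77.1 ± 9.8 kg truncated at ±3 SD, stature 1.78 ± 0.04 m), segment lengths
as standard fractions of stature and circumferences scaled with
√(m/stature), four depths (0.5, 0.85, 1.12, 1.3 m) × four speeds (0.2–0.8
m/s), ≥6 strides per trial at 60 Hz, Gaussian marker noise (default 5 mm,
manual-digitization scale), and breath-by-breath gas exchange at ~3 s
intervals with multiplicative lognormal noise (default CV 5 %) and trial
RER drawn from 0.79–0.87.

Gait waveform: the hip translates at the requested mean speed riding on a
rigid stance strut (93 % of thigh+shank length, leaving knee-flexion
slack), the ankle alternates floor-fixed stance (duty factor 0.65) with a
cycloidal swing (6 cm lift), and the knee follows by two-link inverse
kinematics.  Stride length follows SL = (0.5 + 0.5·v)·(stature/1.78),
chosen to span the 0.6–0.9 m range typical of slow immersed walking.  The
walking metabolic record encodes, by exact inversion of the calorimetry
equation, either the participant's own mechanical prediction
(``cot_source="forward_model"``, default) or a supplied quadratic cost
field (``"surface"``) on top of a ~1 MET standing baseline.

What the generator does **not** emulate: fluid–body interaction feeding
back into kinematics (depth does not alter the waveform), joint-angle
realism beyond stride-integrated quantities, inter-stride variability,
anaerobic or thermoregulatory components, and the absolute drag magnitudes
of real immersed gait (the template's swing speeds, and the 4.5 Hz filter,
give condition-mean DrF below values measured in humans).  Passing tests
therefore demonstrate internal consistency and correctness of the
computational chain, not predictive accuracy on human data.

## Numerical choices and reproducibility

Velocities are `numpy.gradient` central differences; strip velocities are
derivatives of reconstructed strip positions, keeping them exactly
consistent with the markers.  Two-link inverse kinematics clamps the
hip–ankle distance into the reachable annulus.  Iso-cost roots must pass a
|A−B| residual check; identical curves are flagged degenerate rather than
rooted.  All random stages are pure functions of (config, seed); child
seeds derive from `numpy.random.SeedSequence` and stay below 2³¹.  Each
pipeline run writes a provenance block (config hash, seed, version).

Problem sizes in the shipped test suite: the pipeline tests use 3
participants on a 3×3 condition grid with 3 analyzed strides; the
end-to-end recovery and cross-validation properties run the full 9×16
study grid noise-free; bootstrap coverage uses 200 simulated cohorts of
24 units × 16 rows at 1 000 iterations each.

## Known limitations

- Percentile bootstrap CIs undercover with very few clusters: measured
  coverage at the study's nine participants is ~85–89 % for a nominal
  95 % interval, independent of effect size or noise structure.  The
  coverage property is therefore validated at 24 units (~94 % measured);
  intervals reported for nine-participant runs should be read as slightly
  anti-conservative.
- DrF aggregation as a stride-time average is one of several readings of a
  "summed over strips and phases" prescription; the impulse-per-length
  alternative is implemented but changes absolute work levels.
- The weight-bearing table is a five-node calibration reproducing printed
  equivalent-gravity levels, not the original literature table; supply a
  CSV to override it.
- Self-selected-speed summaries can be computed from a cohort-mean surface
  or per participant and averaged; the two differ on noisy data and
  neither is presumed authoritative.
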