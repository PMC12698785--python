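"""Published reference values for shallow-water walking energetics.

These constants describe the study conditions the synthetic cohort
emulates: the four landmark immersion depths and nominal treadmill-free
speeds, cohort anthropometric distributions, the condition-mean cost of
transport and kinetic summaries, and the coefficients of the published
quadratic COT response surface

    COT(s, d) = 1.22 s^2 + 9.96 d^2 + 17.93 s d - 8.17 s - 20.95 d + 10.52

with speed s in m/s, immersion depth d in m, COT in J/kg/m.  They are data
inputs — nothing in the package derives results from them except where a
published value is explicitly the ground truth being emulated or checked.
"""

from __future__ import annotations

#: Quadratic surface coefficients in the order
#: (speed^2, depth^2, speed*depth, speed, depth, intercept).
SURFACE_COEFFICIENTS = (1.22, 9.96, 17.93, -8.17, -20.95, 10.52)

#: 95% confidence intervals printed with the surface coefficients.
SURFACE_COEFFICIENT_CI = (
    (-7.1715, 9.6177),
    (5.3278, 14.5990),
    (12.7915, 23.0697),
    (-18.4388, 2.0991),
    (-29.8331, -12.0496),
    (5.6813, 15.3491),
)

#: Immersion depths (m) of the four landmark conditions at the study pool.
STUDY_DEPTHS = {"knee": 0.5, "hip": 0.85, "umbilicus": 1.12, "xiphoid": 1.3}

#: Nominal target walking speeds (m/s).
NOMINAL_SPEEDS = (0.2, 0.4, 0.6, 0.8)

#: Fit/evaluation domain of the surface.
SPEED_BOUNDS = (0.2, 0.8)
DEPTH_BOUNDS = (0.5, 1.3)

#: Condition-mean measured cost of transport (J/kg/m), depth -> per speed.
CONDITION_MEAN_COT = {
    "knee": (2.7, 2.8, 3.3, 4.4),
    "hip": (1.3, 3.3, 4.3, 6.0),
    "umbilicus": (2.8, 4.7, 7.2, 9.6),
    "xiphoid": (2.7, 5.9, 9.8, 12.1),
}

#: Condition-mean stride drag force DrF (N), depth -> per speed.
CONDITION_MEAN_DRF = {
    "knee": (8.7, 22.0, 38.6, 58.7),
    "hip": (13.0, 38.8, 74.0, 111.3),
    "umbilicus": (20.9, 67.1, 115.9, 170.9),
    "xiphoid": (19.0, 76.0, 126.3, 148.9),
}

#: Cohort-mean stride vertical GRF (N) per depth.
CONDITION_MEAN_GRF = {"knee": 666.7, "hip": 419.6, "umbilicus": 352.7, "xiphoid": 244.3}

#: Equivalent gravity (g-units) of each landmark depth.
GRAVITY_EQUIVALENTS = {"knee": 0.88, "hip": 0.58, "umbilicus": 0.48, "xiphoid": 0.33}

#: Mean self-selected walking speed (m/s) per depth.
SELF_SELECTED_SPEEDS = {"knee": 0.62, "hip": 0.54, "umbilicus": 0.49, "xiphoid": 0.43}

#: Cohort anthropometric distributions (mean, SD).
COHORT_MASS = (77.1, 9.8)  # kg
COHORT_STATURE = (1.78, 0.04)  # m

#: Mean respiratory exchange ratio band across walking speeds.
RER_BAND = (0.79, 0.87)
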