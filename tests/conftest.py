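import numpy as np
import pandas as pd
import pytest

from hydrogait.body_model import build_segment_model
from hydrogait.gait_kinematics import (
    LANDMARKS,
    MarkerTrajectorySet,
    detect_strides,
    filter_markers,
    segment_states,
)
from hydrogait.synthetic_cohort import CohortConfig, generate_cohort, generate_gait_trial


@pytest.fixture(scope="session")
def noiseless_config():
    """Deterministic study-condition config with all noise switched off.

    Statures are pinned to the cohort mean so the synthetic stride period
    is an exact number of 60 Hz samples and strides are strictly periodic.
    """
    return CohortConfig(
        seed=11, mass_sd=0.0, stature_sd=0.0,
        marker_noise_sd=0.0, metabolic_noise_cv=0.0,
    )


@pytest.fixture(scope="session")
def cohort(noiseless_config):
    return generate_cohort(noiseless_config)


@pytest.fixture(scope="session")
def participant(cohort):
    return cohort[0][0]


@pytest.fixture(scope="session")
def frusta(participant):
    return build_segment_model(participant)


@pytest.fixture(scope="session")
def trial(participant, noiseless_config):
    """Noiseless hip-depth trial at 0.6 m/s (stride period exactly 80 samples)."""
    return generate_gait_trial(participant, 0.85, 0.6, noiseless_config, seed=42)


@pytest.fixture(scope="session")
def filtered_trial(trial):
    return filter_markers(trial)


@pytest.fixture(scope="session")
def strides(filtered_trial):
    return detect_strides(filtered_trial)


@pytest.fixture(scope="session")
def states(filtered_trial):
    return segment_states(filtered_trial)


def make_markers(n: int, fs: float = 60.0, **overrides) -> MarkerTrajectorySet:
    """Hand-built marker set: a plausible static posture unless overridden.

    ``overrides`` maps column names (e.g. ``calcaneus_y``) to arrays.
    """
    base = {
        "fifth_metatarsal": (0.15, 0.01),
        "calcaneus": (-0.05, 0.01),
        "lateral_malleolus": (0.0, 0.07),
        "femoral_epicondyle": (0.0, 0.50),
        "greater_trochanter": (0.0, 0.93),
        "umbilicus": (0.01, 1.11),
        "xiphoid": (0.02, 1.29),
    }
    data = {}
    for lm in LANDMARKS:
        x0, y0 = base[lm]
        data[f"{lm}_x"] = np.full(n, x0, dtype=float)
        data[f"{lm}_y"] = np.full(n, y0, dtype=float)
    data.update({k: np.asarray(v, dtype=float) for k, v in overrides.items()})
    return MarkerTrajectorySet(
        sampling_rate=fs, time=np.arange(n) / fs, data=pd.DataFrame(data)
    )
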