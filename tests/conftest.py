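import numpy as np
import pandas as pd
import pytest

from thermosocial import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset shared across tests."""
    cfg = GeneratorConfig(n_events_per_type=8, n_baseline_events=40, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_config():
    """Generator config with every stochastic term switched off."""
    return GeneratorConfig(
        n_events_per_type=4,
        n_baseline_events=4,
        cluster_sds={"A": 0.0, "B": 0.0, "C": 0.0, "baseline": 0.0},
        cluster_subject_sds={"A": 0.0, "B": 0.0, "C": 0.0, "baseline": 0.0},
        subject_sd=0.0,
        picture_sd=0.0,
        movement_effects={"no_movement": 0.0, "steps": 0.0, "travel": 0.0},
        ambient_slope=0.0,
        angle_bias={a: 0.0 for a in
                    ("facing", "quarter_left", "quarter_right", "profile_left",
                     "profile_right", "rear_left", "rear_right")},
        audience_effects={"alpha_presence_cooperative": 0.0,
                          "female_count_competitive": 0.0,
                          "male_count_copulation": 0.0,
                          "mother_presence_copulation": 0.0},
        seed=5,
    )


def make_lmm_frame(rng: np.random.Generator, n: int = 200, beta_x: float = 0.0,
                   subject_sd: float = 0.1, n_subjects: int = 6,
                   resid_sd: float = 0.2) -> pd.DataFrame:
    """Simple random-intercept data for mixed-model tests."""
    subj = rng.integers(0, n_subjects, n)
    x = rng.normal(size=n)
    intercepts = rng.normal(0.0, subject_sd, n_subjects)
    y = 1.0 + beta_x * x + intercepts[subj] + rng.normal(0.0, resid_sd, n)
    return pd.DataFrame({
        "log_temp": y,
        "x": x,
        "subject_id": [f"S{i}" for i in subj],
        "ambient_centered": rng.normal(size=n),
    })
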