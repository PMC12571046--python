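import numpy as np
import pandas as pd
import pytest

from motr.design import StudyPlan, make_design
from motr.generate import GenerativeParams, simulate_measures, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Four-participant simulated study with raw trajectories."""
    return simulate_study(StudyPlan(n_participants=4), seed=11)


@pytest.fixture(scope="session")
def sim_measures():
    """Simulated critical-region total durations, 32 participants."""
    design = make_design(StudyPlan(n_participants=32), seed=1)
    meas, truth = simulate_measures(design, GenerativeParams(), None, "lognormal", rng=42)
    return meas, truth


@pytest.fixture(scope="session")
def five_word_layout():
    return pd.DataFrame(
        {
            "trial": "t",
            "word_index": np.arange(5),
            "text": list("abcde"),
            "x_min": np.arange(5) * 100.0,
            "x_max": np.arange(5) * 100.0 + 80.0,
            "y_min": 0.0,
            "y_max": 30.0,
            "region": np.arange(1, 6),
        }
    )
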