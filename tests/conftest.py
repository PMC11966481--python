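import numpy as np
import pandas as pd
import pytest

from corticalmark import SimulationConfig, make_toy_atlas, simulate_regional_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_atlas():
    return make_toy_atlas((12, 12, 12), 2, seed=1)


@pytest.fixture
def random_centroids():
    """34 generic unit-sphere centroids (no special geometry)."""
    g = np.random.default_rng(42).normal(size=(34, 3))
    return g / np.linalg.norm(g, axis=1, keepdims=True)


@pytest.fixture
def small_cohort():
    cfg = SimulationConfig(n_cases=40, n_controls=40, region_count=6, planted_d=-0.4, seed=5)
    return simulate_regional_cohort(cfg)


def make_table(measures: np.ndarray, dx, age=None, sex=None, severity=None):
    """Hand-built RegionalMeasureTable for unit tests."""
    from corticalmark import RegionalMeasureTable

    measures = np.atleast_2d(np.asarray(measures, float))
    n = measures.shape[0]
    dx = np.asarray(dx, int)
    subjects = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "age": np.zeros(n) if age is None else np.asarray(age, float),
            "sex": np.zeros(n, int) if sex is None else np.asarray(sex, int),
            "dx": dx,
            "severity": np.full(n, np.nan) if severity is None else np.asarray(severity, float),
        }
    )
    cols = [f"r{j}" for j in range(measures.shape[1])]
    return RegionalMeasureTable(subjects, pd.DataFrame(measures, columns=cols))
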