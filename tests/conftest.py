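import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def blend_table():
    from scentdiel.datasets import load_blend_table

    return load_blend_table()


@pytest.fixture(scope="session")
def small_truth():
    """Compact ground truth: one ion per timing class."""
    from scentdiel.simulate import default_truth

    return default_truth(n_morning=1, n_afternoon=1, n_dark=1, seed=7)


@pytest.fixture(scope="session")
def schedule():
    from scentdiel.simulate import LightSchedule

    return LightSchedule(n_days=3)


@pytest.fixture
def simple_ladder():
    return pd.DataFrame(
        {"carbon_number": [7, 8, 9, 10], "rt_min": [8.0, 10.0, 12.0, 14.5]}
    )


@pytest.fixture(scope="session")
def clustered_composition():
    """Two well-separated composition clusters (between/within ratio ~100)."""
    rng = np.random.default_rng(11)
    n = 8
    base_a = np.array([10.0, 1.0, 0.5, 0.1])
    base_b = np.array([0.5, 0.2, 8.0, 6.0])
    rows = [base_a + rng.normal(0, 0.05, 4) for _ in range(n)]
    rows += [base_b + rng.normal(0, 0.05, 4) for _ in range(n)]
    X = np.clip(np.array(rows), 0, None)
    groups = np.repeat(["a", "b"], n)
    return pd.DataFrame(X, columns=list("wxyz")), pd.DataFrame({"group": groups})
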