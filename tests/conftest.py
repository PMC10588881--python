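import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from prlink.blocking import block
from prlink.pipeline import train_default_scorer
from prlink.preprocess import standardize_table
from prlink.scoring import ModelSpec
from prlink.simulate import SimulationConfig, generate_dataset_pair

SMALL_GRID = {"learning_rate": [0.1], "max_depth": [5], "n_estimators": [100]}


@pytest.fixture(scope="session")
def small_pair():
    """A 800-row simulated pair with moderate overlap and degradation."""
    return generate_dataset_pair(SimulationConfig(800, 0.3, 0.2, seed=7))


@pytest.fixture(scope="session")
def small_std(small_pair):
    return (
        standardize_table(small_pair.table_a),
        standardize_table(small_pair.table_b),
    )


@pytest.fixture(scope="session")
def small_candidates(small_std):
    return block(*small_std)


@pytest.fixture(scope="session")
def quick_scorer():
    """Shared scorer with a single-point grid (fast; full grid is
    exercised in the acceptance suite)."""
    return train_default_scorer(seed=0, model_spec=ModelSpec(grid=SMALL_GRID, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
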