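import numpy as np
import pytest

from fallban import evaluation as ev
from fallban import features as ft
from fallban import synthetic as syn
from fallban.types import MOVEMENT_TYPES


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced dataset: 4 executions of each of the 14 movement types."""
    config = syn.GeneratorConfig(counts={m: 4 for m in MOVEMENT_TYPES}, seed=7)
    return syn.synth_dataset(config)


@pytest.fixture(scope="session")
def full_dataset():
    """Default study conditions: 746 trials across 14 movement types."""
    return syn.synth_dataset(syn.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def full_table(full_dataset):
    return ft.feature_table(full_dataset)


@pytest.fixture(scope="session")
def full_split(full_table):
    return ev.split_dataset(full_table, ev.SplitPlan(seed=1))


@pytest.fixture(scope="session")
def full_grid_results(full_table, full_split):
    """Metric series of the complete factorial grid (4 x 63 x 31 x 6)."""
    grid = ev.ExperimentGrid()
    return ev.run_factorial_experiment(full_table, grid, full_split)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
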