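import numpy as np
import pandas as pd
import pytest

from reefrestore.brt_engine import BRTConfig
from reefrestore.synthetic_data import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic world shared across tests."""
    cfg = SimulationConfig(n_localities=400, restored_fraction=0.12, seed=11,
                           spatial_range_km=250.0, spatial_sd=0.8)
    return generate_dataset(cfg)


@pytest.fixture()
def fast_classifier_config():
    return BRTConfig(learning_rate=0.05, bag_fraction=0.5, tree_complexity=3,
                     n_trees_range=(50, 250), n_trees_step=10, n_folds=3,
                     loss="bernoulli")


@pytest.fixture()
def fast_regressor_config():
    return BRTConfig(learning_rate=0.05, bag_fraction=0.7, tree_complexity=3,
                     n_trees_range=(50, 250), n_trees_step=10, n_folds=3,
                     loss="squared")


@pytest.fixture()
def scattered_points():
    """80 well-separated points (several degrees apart) with ids."""
    rng = np.random.default_rng(5)
    lon = rng.uniform(-170, 170, 80)
    lat = rng.uniform(-25, 25, 80)
    return pd.DataFrame({"id": np.arange(80), "lon": lon, "lat": lat})
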