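import numpy as np
import pytest

from mvmdm import pipeline
from mvmdm.model import MVMDM


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled phantom geometry used throughout the unit tests."""
    return pipeline.phantom_config("test")


@pytest.fixture(scope="session")
def effect_run():
    """One full scaled run at strong class separation (effect 0.6):
    40 training / 20 held-out subjects, all three routes plus the ensemble.
    Shared across tests because training the 3D route dominates runtime."""
    model = MVMDM.from_phantom(n_train_per_class=20, n_test_per_class=10, effect=0.6, seed=11)
    return model.fit(seed=11)


@pytest.fixture(scope="session")
def null_run():
    """Full scaled run with exchangeable classes (effect 0): 40 training
    subjects, 100 held-out subjects for the calibration check."""
    model = MVMDM.from_phantom(n_train_per_class=20, n_test_per_class=50, effect=0.0, seed=3)
    return model.fit(seed=3)
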