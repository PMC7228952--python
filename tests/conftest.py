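import numpy as np
import pytest

from axodense.synthetic import SyntheticNerveConfig, generate_dataset
from axodense.training import build_training_samples


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Desk-scale study conditions shared by the training-dependent tests:
# 10 nerves x 10 images at reduced (128 px) resolution, axon density scaled
# from the 187-px standard by image area, split 60-20-20 at the nerve level.
# ---------------------------------------------------------------------------

DESK_CONFIG = SyntheticNerveConfig(
    image_size_px=128, axon_density=19.0, damage_level=0.15, seed=0
)
DESK_SEED = 42


@pytest.fixture(scope="session")
def desk_dataset():
    return generate_dataset(
        10, 10, config=DESK_CONFIG, seed=DESK_SEED, density_spread=0.7
    )


@pytest.fixture(scope="session")
def desk_samples(desk_dataset):
    return {
        name: build_training_samples(desk_dataset[name])
        for name in ("train", "val", "test")
    }


@pytest.fixture(scope="session")
def trained_regressor(desk_samples):
    """A density regressor trained under the desk-scale conditions.

    Shared by the tiling and recovery tests; the 10-epoch schedule uses
    the desk-scale learning rate (see docs/methods.md).
    """
    from axodense.regressor import AxonDensityRegressor

    tr = desk_samples["train"]
    est = AxonDensityRegressor(
        base_filters=16, epochs=10, learning_rate=1e-3, augment=False, seed=7
    )
    est.fit([s.image for s in tr], [s.target for s in tr])
    return est
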