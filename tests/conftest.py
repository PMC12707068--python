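import numpy as np
import pytest
from hypothesis import settings

from consplan.grid import BinaryLayer, GridSpec
from consplan.synthetic import NetworkSpec, WorldConfig, generate_world

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def small_config(seed: int = 42, **kwargs) -> WorldConfig:
    """A fast-to-generate world preserving the default structure."""
    defaults = dict(
        n_rows=60,
        n_cols=60,
        n_provinces=12,
        networks={
            "PA": NetworkSpec(count=25, area_median=12.0, area_sigma=0.7),
            "OECM": NetworkSpec(count=5, area_median=8.0),
            "BR": NetworkSpec(
                count=10,
                area_median=10.0,
                buffer_only_fraction=0.26,
                overlap_partner="PA+OECM",
                overlap_target=0.35,
            ),
        },
        seed=seed,
    )
    defaults.update(kwargs)
    return WorldConfig(**defaults)


@pytest.fixture(scope="session")
def small_world():
    return generate_world(small_config())


@pytest.fixture
def unit_grid():
    """10x10 all-land unit-area grid."""
    return GridSpec(10, 10)


def make_mask(grid: GridSpec, rng: np.random.Generator, p: float = 0.3) -> BinaryLayer:
    return BinaryLayer(grid, rng.random(grid.shape) < p, name="rand")
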