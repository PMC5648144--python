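import numpy as np
import pytest

from enmfactorial.raster import GridLayer, GridStack
from enmfactorial.synth import WorldConfig, gen_environment


def make_layer(values, origin=(-10.0, 10.0), cell_size=0.5, name="layer"):
    values = np.asarray(values, dtype=float)
    return GridLayer(
        name=name,
        values=values,
        valid=np.isfinite(values),
        origin_x=origin[0],
        origin_y=origin[1],
        cell_size=cell_size,
    )


@pytest.fixture(scope="session")
def small_world():
    """A 60x60 synthetic world shared by the slower integration tests."""
    cfg = WorldConfig(shape=(60, 60), seed=11, mask_hole_fraction=0.03)
    climate, edaphic = gen_environment(cfg)
    return cfg, climate, edaphic


@pytest.fixture
def toy_stack():
    rng = np.random.default_rng(3)
    layers = [
        make_layer(rng.standard_normal((8, 8)), name=f"v{i}") for i in range(3)
    ]
    return GridStack(layers)
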