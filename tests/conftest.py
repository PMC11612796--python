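"""Shared fixtures: one default population and raster reused across tests."""

import numpy as np
import pytest

from onspv.encoding import build_rf_stack
from onspv.geometry import SceneGeometry
from onspv.rgc_population import build_population
from onspv.scenes import DepthGrayMap, colorize_instances, generate_static_fixture


@pytest.fixture(scope="session")
def pop10k():
    """Default 10,000-cell population (the reference problem size)."""
    return build_population(n=10000, seed=1)


@pytest.fixture(scope="session")
def geom_small():
    """Reduced raster (same FOV as the default geometry) to keep tests fast."""
    return SceneGeometry(width=320, height=240)


@pytest.fixture(scope="session")
def stack_small(pop10k, geom_small):
    return build_rf_stack(pop10k, geom_small)


@pytest.fixture(scope="session")
def fixture_scenes(geom_small):
    """Five synthetic table-setting scenes with four objects each."""
    scenes = []
    for seed in range(5):
        inst, _ = generate_static_fixture(4, setting="table", seed=seed, geometry=geom_small)
        scenes.append(colorize_instances(inst, DepthGrayMap(setting="table")))
    return scenes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
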