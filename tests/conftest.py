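import numpy as np
import pytest

from dermoptics import (
    ChromophoreLibrary,
    RenderConfig,
    ScatteringParams,
    TissueParams,
    build_reflectance_lut,
)


@pytest.fixture(scope="session")
def lib():
    return ChromophoreLibrary.default()


@pytest.fixture(scope="session")
def tissue():
    return TissueParams()


@pytest.fixture(scope="session")
def scatter():
    return ScatteringParams()


@pytest.fixture(scope="session")
def render_cfg():
    return RenderConfig.default()


@pytest.fixture(scope="session")
def lut(tissue, scatter, lib, render_cfg):
    """Default-grid reflectance LUT shared across the suite."""
    return build_reflectance_lut(tissue, scatter, lib, render_cfg)


@pytest.fixture(scope="session")
def small_lut(tissue, scatter, lib, render_cfg):
    return build_reflectance_lut(tissue, scatter, lib, render_cfg, grid_sizes=(16, 16))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
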