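import numpy as np
import pytest

from foldconn import GeneratorConfig, RoiSet


@pytest.fixture
def rois64():
    return RoiSet.canonical(32)


@pytest.fixture
def small_config():
    """Desk-scale generator settings: short acquisition, default dynamics."""
    return GeneratorConfig(duration_s=120.0, n_per_group=5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
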