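import numpy as np
import pytest

from cxrsim import PhantomSpec, default_pool, generate_thorax_phantom, remove_table, segment_lung


@pytest.fixture(scope="session")
def phantom_with_masks():
    """Default 128^3 thorax phantom plus its truth masks."""
    return generate_thorax_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def phantom_volume(phantom_with_masks):
    return phantom_with_masks[0]


@pytest.fixture(scope="session")
def truth_masks(phantom_with_masks):
    return phantom_with_masks[1]


@pytest.fixture(scope="session")
def clean_volume(phantom_volume):
    """Phantom with the table removed."""
    return remove_table(phantom_volume)


@pytest.fixture(scope="session")
def lung_mask(clean_volume):
    return segment_lung(clean_volume)


@pytest.fixture(scope="session")
def shape_pool():
    return default_pool(seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
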