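import numpy as np
import pytest

from wmhseg import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One 48-cube phantom with moderate load, shared across tests."""
    spec = PhantomSpec(grid_shape=(48, 48, 48), lesion_load_target=0.03, seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def artifact_phantom():
    """Phantom with planted cortical bright spots and a flow artefact."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 48), lesion_load_target=0.04,
        periventricular_fraction=0.7, plant_cortical_artifacts=True, seed=21,
    )
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
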