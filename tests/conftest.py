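import numpy as np
import pytest
from hypothesis import settings

from renomorph import default_profiles
from renomorph.synthetic import TissueSpec, render_tissue

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def panel():
    """One default rendered stain panel, shared across tests."""
    return render_tissue(TissueSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
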