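import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pencil_cuvette_model():
    """Cuvette forward model with an ideal pencil source (fast, shared)."""
    from goniotwin.forward import cuvette_model, pencil_source

    return cuvette_model(source=pencil_source(), is_frac=0.25)


@pytest.fixture(scope="session")
def cuvette_truth_signal(pencil_cuvette_model):
    """A moderately deep forward run of the reference cuvette scenario."""
    return pencil_cuvette_model.simulate(0.1, 0.15, 0.75, 8_000_000, 4242)
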