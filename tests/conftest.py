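import numpy as np
import pytest

from ivea.engine import run_inference
from ivea.simulate import make_fixture


@pytest.fixture(scope="session")
def tiny_ds():
    return make_fixture("tiny", seed=1)


@pytest.fixture(scope="session")
def medium_ds():
    return make_fixture("medium", seed=1)


@pytest.fixture(scope="session")
def degenerate_ds():
    return make_fixture("degenerate", seed=1)


@pytest.fixture(scope="session")
def tiny_input(tiny_ds):
    return tiny_ds.to_inference_input()


@pytest.fixture(scope="session")
def medium_input(medium_ds):
    return medium_ds.to_inference_input()


@pytest.fixture(scope="session")
def degenerate_input(degenerate_ds):
    return degenerate_ds.to_inference_input()


@pytest.fixture(scope="session")
def medium_state(medium_input):
    return run_inference(medium_input)


@pytest.fixture(scope="session")
def tiny_state(tiny_input):
    return run_inference(tiny_input)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
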