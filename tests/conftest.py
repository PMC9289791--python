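import numpy as np
import pytest
from hypothesis import settings

from engfeat.preprocess import WindowSpec
from engfeat.pipeline import extract_features
from engfeat.synthdata import generate_easy_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def easy_rec():
    """Small strongly-separable synthetic recording (120 stimuli, 4 ch)."""
    return generate_easy_fixture(seed=7)


@pytest.fixture(scope="session")
def easy_stw_features(easy_rec):
    """STW feature matrix of the easy fixture at the default 175 ms / 20%
    window; shared because it is the most expensive artifact in the suite."""
    return extract_features(easy_rec, "stw", WindowSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
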