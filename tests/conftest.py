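import numpy as np
import pytest

from flexfold.synthetic import build_toy_pentamer, make_bundle, restraints_from_bundle


@pytest.fixture(scope="session")
def bundle():
    """Noiseless default synthetic bundle, shared across the suite."""
    return make_bundle(0)


@pytest.fixture(scope="session")
def truth(bundle):
    return bundle.truth


@pytest.fixture(scope="session")
def bundle_restraints(bundle):
    return restraints_from_bundle(bundle)


@pytest.fixture(scope="session")
def toy_pentamer():
    return build_toy_pentamer(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
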