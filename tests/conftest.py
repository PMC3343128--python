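import numpy as np
import pytest

from nettension import build_model
from nettension.data import reference_meta, reference_params


@pytest.fixture(scope="session")
def base_model():
    return build_model("base")


@pytest.fixture(scope="session")
def dup_model():
    return build_model("dup_e2f")


@pytest.fixture(scope="session")
def nominal():
    """Bundled reference bistable parameter set (base variant)."""
    return reference_params("reference_bistable")


@pytest.fixture(scope="session")
def nominal_meta():
    return reference_meta("reference_bistable")


@pytest.fixture(scope="session")
def biphasic_fixture():
    return reference_params("reference_biphasic")


@pytest.fixture(scope="session")
def adaptive_fixture():
    return reference_params("reference_adaptive")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
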