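import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vdjnmd.gene_models import make_reference_fixture
from vdjnmd.ptc_annotate import Annotator, EjcParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture():
    """Default paired A/F reference fixture (deterministic, seed 0)."""
    return make_reference_fixture()


@pytest.fixture(scope="session")
def annotators(fixture):
    return {g: Annotator(fixture.models[g], EjcParams()) for g in ("A", "F")}


@pytest.fixture()
def rng():
    return np.random.default_rng(20110713)
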