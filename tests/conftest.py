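import pytest
from hypothesis import settings

from rcc5align import fossil_matrix, scelianoma_problem

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def scelianoma():
    return scelianoma_problem()


@pytest.fixture(scope="session")
def fossils():
    return fossil_matrix()
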