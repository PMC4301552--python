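import pytest
from hypothesis import HealthCheck, settings

from genemeta import builtin_fixture

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rs2808630():
    return builtin_fixture("rs2808630")


@pytest.fixture(scope="session")
def rs1417938():
    return builtin_fixture("rs1417938")
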