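import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from ctdnaval import fixtures, simulate  # noqa: E402


@pytest.fixture(scope="session")
def table3_rows():
    return fixtures.load_table3()


@pytest.fixture(scope="session")
def truth_panel():
    return simulate.make_reference_panel(0)


@pytest.fixture(scope="session")
def reference_indels():
    return fixtures.load_reference_indels()
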