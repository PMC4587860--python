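import pytest
from hypothesis import HealthCheck, settings

import orchidmatk as om

settings.register_profile(
    "ci", max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exemplar() -> om.AicExemplar:
    """The canonical orchid aic fixture (ATGT insertion + compensatory set)."""
    return om.aic_exemplar()


@pytest.fixture(scope="session")
def reference() -> om.Reference:
    """A mid-sized clean reference shared by tests that do not need 510 codons."""
    return om.generate_reference_cds(len_codons=200, seed=42)
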