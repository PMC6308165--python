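import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CHMAP28 = "GRFKRFRKKLKRLWHKVGPFVGPILHY"
MELITTIN = "GIGAVLKVLTTGLPALISWIKRKRQQ"


@pytest.fixture
def chmap28():
    from amptox import parse_peptide

    return parse_peptide(CHMAP28, name="ChMAP-28")


@pytest.fixture
def melittin():
    from amptox import parse_peptide

    return parse_peptide(MELITTIN, name="melittin")
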