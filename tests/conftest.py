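import pytest
from hypothesis import HealthCheck, settings

from splintlig.design import DesignConstraints, design_oligo_set
from splintlig.examples import worked_template

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def template():
    """The worked 620-nt library template (20 NNK codons, 3'-constant tail)."""
    return worked_template()


@pytest.fixture(scope="session")
def constraints():
    return DesignConstraints()


@pytest.fixture(scope="session")
def designed(template, constraints):
    """Full design of the worked template: sense oligos + splints + CR."""
    return design_oligo_set(template, constraints)
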