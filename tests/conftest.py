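import pytest

from telecost import (
    CostParameters,
    EmissionModel,
    default_config,
    generate_cohort,
    reference_aggregates,
)


@pytest.fixture(scope="session")
def params():
    return CostParameters()


@pytest.fixture(scope="session")
def emodel():
    return EmissionModel()


@pytest.fixture(scope="session")
def ref_aggs():
    """(telemedicine, control) published group statistics."""
    return reference_aggregates()


@pytest.fixture(scope="session")
def small_cohort():
    """52-record synthetic cohort under study-condition defaults."""
    return generate_cohort(default_config(seed=7))
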