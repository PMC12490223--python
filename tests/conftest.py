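import pytest

from neobasket.design import DesignSpec, ExceedanceCache
from neobasket.patients import assign_analysis_sets, load_patients


@pytest.fixture(scope="session")
def records():
    return load_patients()


@pytest.fixture(scope="session")
def sets(records):
    return assign_analysis_sets(records)


@pytest.fixture(scope="session")
def published_design():
    return DesignSpec.published()


@pytest.fixture(scope="session")
def shared_cache(published_design):
    """One exceedance cache for every design-simulation test in the session."""
    return ExceedanceCache(published_design)
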