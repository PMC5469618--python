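import pytest

from ihmburden import fixtures
from ihmburden.variants import annotate


@pytest.fixture(scope="session")
def regions():
    return fixtures.load_regions()


@pytest.fixture(scope="session")
def hcm_tables():
    return (fixtures.load_hcm_pv_table(), fixtures.load_hcm_lpv_table())


@pytest.fixture(scope="session")
def dcm_table():
    return fixtures.load_dcm_table()


@pytest.fixture(scope="session")
def hcm_annotated(regions):
    return annotate(fixtures.hcm_records(("PV", "LPV")), regions)


@pytest.fixture(scope="session")
def hcm_pv_annotated(regions):
    return annotate(fixtures.hcm_records(("PV",)), regions)


@pytest.fixture(scope="session")
def dcm_annotated(regions):
    return annotate(fixtures.dcm_records(), regions)
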