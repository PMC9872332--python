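import pytest

from karyopaint import load_fixture


@pytest.fixture(scope="session")
def tml_tin_map():
    return load_fixture("tml_tin")


@pytest.fixture(scope="session")
def apk_matrix():
    return load_fixture("apk_matrix")


@pytest.fixture(scope="session")
def karyo_tin():
    return load_fixture("karyotype_TIN")


@pytest.fixture(scope="session")
def karyo_tml():
    return load_fixture("karyotype_TML")


@pytest.fixture(scope="session")
def published_associations():
    return load_fixture("hsa_assoc_published")
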