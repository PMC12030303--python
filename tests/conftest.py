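import pytest

from panfam import (
    classify_all,
    infer_core_profile,
    sisrs_pangenome_fixture,
)


@pytest.fixture(scope="session")
def sisrs_members():
    return sisrs_pangenome_fixture()


@pytest.fixture(scope="session")
def sisrs_profile(sisrs_members):
    return infer_core_profile(sisrs_members)


@pytest.fixture(scope="session")
def sisrs_assignments(sisrs_members, sisrs_profile):
    return classify_all(sisrs_members, sisrs_profile)
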