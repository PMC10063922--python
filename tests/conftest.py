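import pytest

from cllsls import load_catalog, toy_catalog_path


@pytest.fixture(scope="session")
def toy_catalog():
    """Four synthetic subsets spanning all three IGHV clans."""
    return load_catalog(toy_catalog_path())


@pytest.fixture(scope="session")
def toy_by_id(toy_catalog):
    return {s.subset_id: s for s in toy_catalog}
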