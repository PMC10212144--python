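import pytest

from nrpsarch.catalog import load_catalog
from nrpsarch.subtypes import load_subtype_models


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def models():
    return load_subtype_models()


@pytest.fixture(scope="session")
def msa_dir():
    from nrpsarch.subtypes import _msa_dir

    return _msa_dir()
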