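import pytest

from ccbmd import load_fixture


@pytest.fixture(scope="session")
def bladder():
    return load_fixture("bladder")


@pytest.fixture(scope="session")
def lung():
    return load_fixture("lung")


@pytest.fixture(scope="session")
def all_datasets(bladder, lung):
    return bladder + lung


@pytest.fixture(scope="session")
def pu(bladder):
    return next(ds for ds in bladder if ds.study_id == "Pu2007")
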