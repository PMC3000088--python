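import pytest

from ionocov import load_dataset, load_known_issues, validate_dataset


@pytest.fixture(scope="session")
def rows():
    return load_dataset()


@pytest.fixture(scope="session")
def known_issues():
    return load_known_issues()


@pytest.fixture(scope="session")
def report(rows):
    return validate_dataset(rows, tolerance=0.005)
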