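import pytest

import phenossu as ph


@pytest.fixture(scope="session")
def lexicon():
    return ph.default_lexicon()


@pytest.fixture(scope="session")
def schema():
    return ph.default_schema()


@pytest.fixture(scope="session")
def lab_kb():
    return ph.default_lab_kb()


@pytest.fixture(scope="session")
def library():
    return ph.builtin_library()


@pytest.fixture(scope="session")
def small_corpus():
    """A small deterministic synthetic corpus shared across tests."""
    return ph.generate_corpus(ph.GeneratorConfig(n_docs=30, seed=99))
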