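import pytest

from gouania import load_default_key, load_table1_fixture

SLENDER = ("G. pigra", "G. hofrichteri")
STOUT = ("G. adriatica", "G. orientalis", "G. willdenowi")


@pytest.fixture(scope="session")
def table():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def key():
    return load_default_key()
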