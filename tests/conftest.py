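import pytest

from inhalertech import default_bank, default_lexicon, default_ruleset
from inhalertech.rule_engine import DEFAULT_RULES


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def rules():
    return DEFAULT_RULES


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture(scope="session")
def bank():
    return default_bank()
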