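import pytest

from echopairs import load_resources


@pytest.fixture(scope="session")
def resources():
    """The shipped resource bundle, loaded once per test session."""
    return load_resources()
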