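import pytest

from rflpkit.enzymes import builtin_enzymes


@pytest.fixture(scope="session")
def enzymes():
    """The packaged eight-enzyme panel, keyed by name."""
    return builtin_enzymes()
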