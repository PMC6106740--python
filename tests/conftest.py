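import pytest

from biolex import load_theme, generate_fixture
from biolex.core import FormatId

ALL_FORMATS = [f for f in FormatId if f is not FormatId.PLAIN]


@pytest.fixture(scope="session")
def default_theme():
    return load_theme("default")


@pytest.fixture(scope="session")
def hc_theme():
    return load_theme("high-contrast")


@pytest.fixture(scope="session")
def fixture_texts():
    """One seeded generated file per supported format."""
    return {fmt: generate_fixture(fmt, seed=42) for fmt in ALL_FORMATS}
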