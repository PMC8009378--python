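import pytest

from bfbsim import GenomeConfig, build_reference


@pytest.fixture(scope="session")
def ref65():
    """6.5 kb configuration (insertion at 107,830)."""
    return build_reference(GenomeConfig(insertion_pos=107_830, seed=1))


@pytest.fixture(scope="session")
def ref123():
    """12.3 kb configuration (insertion at 101,976)."""
    return build_reference(GenomeConfig(insertion_pos=101_976, seed=1))


@pytest.fixture(scope="session")
def ref463():
    """46.3 kb configuration (insertion at 68,000)."""
    return build_reference(GenomeConfig(insertion_pos=68_000, seed=1))


@pytest.fixture(scope="session")
def ref577():
    """57.7 kb configuration (insertion at 56,740)."""
    return build_reference(GenomeConfig(insertion_pos=56_740, seed=1))
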