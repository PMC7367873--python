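import numpy as np
import pytest

from phosprefs import library_design as ld


@pytest.fixture(scope="session")
def designs():
    return ld.builtin_designs()


@pytest.fixture(scope="session")
def compositions():
    return ld.builtin_compositions()


@pytest.fixture(scope="session")
def uniform_x1_composition():
    """Perfectly uniform 14-residue mixture over the x1 alphabet."""
    pct = 100.0 / 14
    percents = {r: pct for r in sorted(ld.X1_ALPHABET)}
    return ld.IsokineticComposition("uniform_x1", percents)


@pytest.fixture(scope="session")
def recovery_design():
    """Test design with all four N-terminal slots randomized over the x1
    alphabet: a larger theoretical space for parameter-recovery checks."""
    slots = tuple(
        [ld.X1_ALPHABET] * 4
        + [frozenset("ST")]
        + [frozenset("A")] * 4
        + [frozenset("K")]
    )
    return ld.LibraryDesign("rec4", slots)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
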