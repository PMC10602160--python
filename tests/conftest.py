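import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("package", deadline=None, derandomize=True)
settings.load_profile("package")

from isynpro import (
    LigationSpec,
    TREAlphabet,
    TREDefinition,
    load_alphabet,
)


@pytest.fixture(scope="session")
def alphabet():
    """The bundled synthetic 11-element fixture alphabet."""
    return load_alphabet()


@pytest.fixture(scope="session")
def tiny_alphabet():
    """A 3-element alphabet for exhaustive-oracle tests."""
    return TREAlphabet(
        tres=(
            TREDefinition("A", "NFKB", "GGGACTTTCC", 6),
            TREDefinition("B", "NFAT", "GGAAAATTTC", 2),
            TREDefinition("C", "AP1", "TGACTCA", 2),
        ),
        flank5="ACGCGTTCGAACTGCAGGTCGACCATGGAA",
        flank3="TTCGAGCTCGGTACCCGGGGATCCTCTAGT",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_templates(alphabet):
    """A reusable pool of size-selected simulated templates."""
    from isynpro import simulate_ligation

    return simulate_ligation(alphabet, LigationSpec(), 200, seed=7)
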