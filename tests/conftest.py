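import numpy as np
import pytest

from bulbnet.morpho import CellType, Morphology, Section, SectionKind, make_reduced_morphology


@pytest.fixture(scope="session")
def reduced_mc():
    return make_reduced_morphology(CellType.MC)


@pytest.fixture(scope="session")
def reduced_mtc():
    return make_reduced_morphology(CellType.MTC)


@pytest.fixture
def simple_bifurcation():
    """50 um parent branching into two 50 um children."""
    return Morphology(
        [
            Section(0, None, SectionKind.SOMA, 10, 10),
            Section(1, 0, SectionKind.LATERAL, 50, 2),
            Section(2, 1, SectionKind.LATERAL, 50, 1.5),
            Section(3, 1, SectionKind.LATERAL, 50, 1.5),
        ],
        CellType.MC,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
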