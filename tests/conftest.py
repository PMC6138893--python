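import numpy as np
import pytest

from curvemut import load_default_table, load_ura3_cds
from curvemut.landscape import CodingSequence
from curvemut.shape import DinucleotidePropertyTable


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def ura3():
    return load_ura3_cds()


@pytest.fixture(scope="session")
def toy_cds():
    # ATG TGG TGT TAA: Met-Trp-Cys-stop; nonsense sites at 1, 5, 6, 9
    return CodingSequence("toy", "ATGTGGTGTTAA")


@pytest.fixture()
def aa_table():
    """Single-property table: AA scores 2, everything else 0."""
    vec = np.zeros(16)
    vec[0] = 2.0
    return DinucleotidePropertyTable({"aa_only": vec})


@pytest.fixture(scope="session")
def random_genome():
    from curvemut.synthetic import simulate_genome

    return simulate_genome(20000, seed=424242)
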