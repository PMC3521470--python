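import numpy as np
import pytest

from zrhc.pedigree_io import GenotypeMatrix, Pedigree


def make_pedigree(members):
    """members: list of (iid, father, mother, sex) with '0' for founders."""
    return Pedigree.from_rows([("F1", i, f, m, s) for i, f, m, s in members])


@pytest.fixture
def trio():
    """Founder couple with one child."""
    return make_pedigree([("1", "0", "0", 1), ("2", "0", "0", 2), ("3", "1", "2", 1)])


@pytest.fixture
def nuclear2():
    """Founder couple with two children (one local cycle)."""
    return make_pedigree(
        [("1", "0", "0", 1), ("2", "0", "0", 2), ("3", "1", "2", 1), ("4", "1", "2", 2)]
    )


def genotypes(codes):
    return GenotypeMatrix(np.array(codes, dtype=np.int8))
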