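import numpy as np
import pytest

from provean.align import GapPenalties, SubstitutionMatrix
from provean.seqvar import AA20, ProteinSequence
from provean.synthfam import FamilyModel, generate_family


@pytest.fixture(scope="session")
def blosum62() -> SubstitutionMatrix:
    return SubstitutionMatrix.load("BLOSUM62")


@pytest.fixture(scope="session")
def default_gaps() -> GapPenalties:
    return GapPenalties()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20120)


def random_protein(rng: np.random.Generator, length: int) -> str:
    aa = np.array(list(AA20))
    return "".join(aa[rng.integers(0, len(aa), size=length)])


@pytest.fixture(scope="session")
def small_family():
    """A modest synthetic family shared across tests (kept small for speed)."""
    rng = np.random.default_rng(55)
    length = 60
    conserved = frozenset(int(p) + 1 for p in rng.choice(length, size=14, replace=False))
    model = FamilyModel(
        length=length,
        conserved_positions=conserved,
        substitution_rate_free=0.5,
        indel_rate=0.1,
        n_homologs=18,
        n_subfamilies=3,
        seed=55,
    )
    query, homologs = generate_family(model)
    return model, query, homologs
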