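import numpy as np
import pytest

from psgkmer import Dataset, Plant, SequenceRecord, SyntheticSpec, generate
from psgkmer.selection import ForestConfig

#: small forest for unit tests where the contract, not the ranking
#: quality, is under test
SMALL_FOREST = ForestConfig(n_trees=15)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


@pytest.fixture(scope="session")
def balanced_toy() -> Dataset:
    """10 labeled 9-nt records, 5 per class, central C."""
    rng = np.random.default_rng(7)
    records = []
    for i in range(10):
        residues = list(random_sequence(rng, 9))
        residues[4] = "C"
        records.append(
            SequenceRecord(f"t{i}", "".join(residues), label=i % 2)
        )
    return Dataset(records)


@pytest.fixture(scope="session")
def planted_dataset() -> Dataset:
    """200 21-nt windows with a strong planted gapped motif (group B)."""
    spec = SyntheticSpec(
        n_pos=100,
        n_neg=100,
        L=21,
        plants=[Plant("A--CG", 2, 0.9, 0.05)],
        seed=3,
    )
    return generate(spec)


PLANTED_DESCRIPTOR = "FT5:A--CG@2-6"
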