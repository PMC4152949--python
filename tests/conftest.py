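import random

import numpy as np
import pytest

from dhspred import (
    LabeledDataset,
    NEGATIVE,
    POSITIVE,
    NucleotideSequence,
    default_table,
)

ALPHABET = "ACGT"


@pytest.fixture(scope="session")
def table():
    """The packaged six-property table (raw values)."""
    return default_table()


@pytest.fixture(scope="session")
def std_table(table):
    return table.standardize()


def random_residues(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(ALPHABET) for _ in range(length))


def random_sequence(rng: random.Random, length: int, seq_id: str = "seq") -> NucleotideSequence:
    return NucleotideSequence(id=seq_id, residues=random_residues(rng, length))


def make_dataset(sequences, labels, name="test") -> LabeledDataset:
    return LabeledDataset(tuple(sequences), tuple(labels), name=name)


@pytest.fixture
def rng():
    return random.Random(20140819)


@pytest.fixture
def np_rng():
    return np.random.default_rng(20140819)
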