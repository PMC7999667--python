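import random

import numpy as np
import pytest

from acescreen.datasets import SynthConfig, generate_synthetic
from acescreen.pseaac import load_default_property_table
from acescreen.seqio import CANONICAL_AA, Peptide, ProteinRecord


@pytest.fixture(scope="session")
def property_table():
    return load_default_property_table()


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic benchmark for fast model/evaluation tests."""
    return generate_synthetic(SynthConfig(n_pos=120, seed=11))


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The default-condition synthetic benchmark (n_pos=400, seed 0)."""
    return generate_synthetic(SynthConfig(n_pos=400, seed=0))


def random_peptide(rng: random.Random, min_len: int = 2, max_len: int = 50) -> Peptide:
    length = rng.randint(min_len, max_len)
    seq = "".join(rng.choice(CANONICAL_AA) for _ in range(length))
    return Peptide(id=f"r{rng.randrange(10**9)}", sequence=seq)


def random_protein(rng: random.Random, length: int, accession: str = "SYN") -> ProteinRecord:
    seq = "".join(rng.choice(CANONICAL_AA) for _ in range(length))
    return ProteinRecord(accession=accession, name="synthetic protein", sequence=seq)


@pytest.fixture
def rng():
    return random.Random(20240550)


@pytest.fixture
def nprng():
    return np.random.default_rng(20240550)
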