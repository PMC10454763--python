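import random

import pytest

import strainsig as ss


@pytest.fixture(scope="session")
def rng():
    return random.Random(20240901)


@pytest.fixture(scope="session")
def toy_genomes():
    """Five random 2 kb genomes, n-gram-disjoint at n=21 with near certainty."""
    return ss.generate_genomes(5, 2000, seed=101)


@pytest.fixture(scope="session")
def toy_model(toy_genomes):
    model, report = ss.build_model(toy_genomes, n=21)
    return model


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
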