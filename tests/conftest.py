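import numpy as np
import pytest

from pepga import Individual, Population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_population(fitnesses, peptides=None, length=9):
    """Evaluated population with the given fitness values (peptides are
    synthetic placeholders unless provided)."""
    n = len(fitnesses)
    if peptides is None:
        from pepga import AMINO_ACIDS

        peptides = []
        for i in range(n):
            # distinct deterministic peptides
            peptides.append(
                "".join(AMINO_ACIDS[(i + j) % 20] for j in range(length))
            )
    individuals = [
        Individual(p, fitness=float(f)) for p, f in zip(peptides, fitnesses)
    ]
    return Population(individuals=individuals, size=n)


@pytest.fixture
def population_factory():
    return make_population
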