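"""Peptide genomes and the population lifecycle.

A candidate solution ("individual") is a fixed-length peptide over the 20
proteinogenic amino acids — for MHC class I optimisation a nonamer. The
population holds a fixed number of individuals and is kept free of duplicate
peptides: after every generation, later copies of an already-present peptide
are replaced by fresh random peptides. This purging step preserves genetic
diversity and prevents a single dominant sequence from taking over the
population (genetic drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasiblePopulationError

#: The 20 standard amino acids in fixed alphabetical order. All "random
#: residue" draws index into this string, so the order is part of the
#: reproducibility contract.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Default genome length: MHC class I epitopes are nonamers.
DEFAULT_PEPTIDE_LENGTH = 9

RandomSource = np.random.Generator


def ensure_rng(seed_or_rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce a seed (or an existing generator) into a numpy Generator.

    Identical seeds yield bit-identical random streams; every stochastic
    operation in the package draws from a generator obtained here.
    """
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def validate_peptide(sequence: str, length: int | None = None) -> str:
    """Uppercase and validate a peptide string.

    Raises ValueError on residues outside the 20-letter alphabet or on a
    length mismatch with `length`.
    """
    seq = str(sequence).upper()
    for ch in seq:
        if ch not in AA_INDEX:
            raise ValueError(f"invalid residue {ch!r} in peptide {seq!r}")
    if length is not None and len(seq) != length:
        raise ValueError(f"peptide {seq!r} has length {len(seq)}, expected {length}")
    return seq


def random_peptide(length: int, rng: RandomSource) -> str:
    """Draw a peptide of `length` residues, each uniform over the alphabet."""
    if length < 1:
        raise ValueError(f"peptide length must be >= 1, got {length}")
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


@dataclass
class Individual:
    """A peptide with a lazily assigned fitness.

    `fitness` stays None until the population evaluation step; any operation
    that produces a new peptide (crossover, mutation, purge replacement)
    creates a fresh Individual with fitness unset.
    """

    peptide: str
    fitness: float | None = None
    evaluated_at: int | None = None


@dataclass
class Population:
    individuals: list[Individual] = field(default_factory=list)
    size: int = 100
    generation: int = 0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"population size must be >= 1, got {self.size}")

    def peptides(self) -> list[str]:
        return [ind.peptide for ind in self.individuals]

    def fitnesses(self) -> list[float]:
        return [ind.fitness for ind in self.individuals]  # type: ignore[misc]

    def is_distinct(self) -> bool:
        peps = self.peptides()
        return len(set(peps)) == len(peps)


def init_population(size: int, length: int, rng: RandomSource) -> Population:
    """Random initial population of pairwise-distinct peptides (generation 0)."""
    if size < 1:
        raise ValueError(f"population size must be >= 1, got {size}")
    pop = Population(
        individuals=[Individual(random_peptide(length, rng)) for _ in range(size)],
        size=size,
        generation=0,
    )
    return purge_duplicates(pop, rng)


def purge_duplicates(
    pop: Population, rng: RandomSource, max_draws_per_slot: int = 1000
) -> Population:
    """Replace duplicate peptides with fresh random ones, in place.

    The first occurrence of every peptide is kept untouched; each later
    duplicate is replaced by a random peptide re-drawn until it collides with
    nothing currently in the population. Replaced individuals lose any cached
    fitness. Raises InfeasiblePopulationError when distinctness is impossible
    (sequence space smaller than the population) or the redraw cap is hit.
    """
    if not pop.individuals:
        return pop
    length = len(pop.individuals[0].peptide)
    if len(AMINO_ACIDS) ** length < len(pop.individuals):
        raise InfeasiblePopulationError(
            f"cannot hold {len(pop.individuals)} distinct peptides of length "
            f"{length} over a {len(AMINO_ACIDS)}-letter alphabet"
        )
    seen: set[str] = set()
    duplicate_slots: list[int] = []
    for i, ind in enumerate(pop.individuals):
        if ind.peptide in seen:
            duplicate_slots.append(i)
        else:
            seen.add(ind.peptide)
    for i in duplicate_slots:
        for _ in range(max_draws_per_slot):
            candidate = random_peptide(length, rng)
            if candidate not in seen:
                break
        else:
            raise InfeasiblePopulationError(
                f"no distinct replacement found within {max_draws_per_slot} draws"
            )
        seen.add(candidate)
        pop.individuals[i] = Individual(candidate)
    return pop
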