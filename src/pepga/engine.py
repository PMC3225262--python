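"""The generational GA loop and the operator-combination benchmark sweep.

One run works on a population of (by default) 100 distinct nonamers for a
fixed number of generations (default 50; no early stopping, so that runs
with different operator combinations stay comparable). Generation 1 is the
evaluated random initial population; every later generation is produced by
selection -> pairwise crossover -> per-position mutation -> duplicate purge
-> evaluation. Exactly `population_size` fitness evaluations are spent per
generation, so a full default sweep (7 selection x 6 crossover x 5 scorers x
2 mutation operators = 420 runs of 50 x 100) costs 2,100,000 evaluations.

Per-generation summaries record the median/min/max fitness and the best
individual; the median trajectory is the standard convergence readout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from statistics import median
from typing import Callable, Sequence

import numpy as np

from .core import (
    DEFAULT_PEPTIDE_LENGTH,
    Individual,
    Population,
    ensure_rng,
    init_population,
    purge_duplicates,
)
from .crossover import CrossoverSpec, crossover
from .errors import PepgaError
from .fitness import FitnessFunction
from .mutation import MutationSpec, mutate
from .selection import SelectionSpec, select_parents


@dataclass
class GAConfig:
    """Full parameterisation of one GA run."""

    fitness: FitnessFunction
    selection: SelectionSpec
    crossover: CrossoverSpec
    mutation: MutationSpec
    population_size: int = 100
    generations: int = 50
    peptide_length: int = DEFAULT_PEPTIDE_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError(f"generations must be >= 1, got {self.generations}")
        if self.population_size < 1:
            raise ValueError(
                f"population size must be >= 1, got {self.population_size}"
            )


@dataclass
class GenerationStats:
    """Summary of one evaluated generation (generation index is 1-based)."""

    generation: int
    median: float
    minimum: float
    maximum: float
    best_peptide: str
    best_fitness: float
    evaluations: int


def _evaluate(pop: Population, fitness: FitnessFunction, generation: int) -> int:
    """Score every unevaluated individual; returns the evaluation count."""
    pending = [ind for ind in pop.individuals if ind.fitness is None]
    if fitness.score_batch is not None and pending:
        scores = fitness.score_batch([ind.peptide for ind in pending])
        for ind, s in zip(pending, scores):
            ind.fitness = float(s)
            ind.evaluated_at = generation
    else:
        for ind in pending:
            ind.fitness = float(fitness.score(ind.peptide))
            ind.evaluated_at = generation
    return len(pending)


def _stats(pop: Population, fitness: FitnessFunction, generation: int,
           evaluations: int) -> GenerationStats:
    values = pop.fitnesses()
    best = max(
        range(len(values)),
        key=lambda i: (fitness.oriented(values[i]), -i),
    )
    return GenerationStats(
        generation=generation,
        median=float(median(values)),
        minimum=float(min(values)),
        maximum=float(max(values)),
        best_peptide=pop.individuals[best].peptide,
        best_fitness=float(values[best]),
        evaluations=evaluations,
    )


def run_ga(
    config: GAConfig,
    on_generation: Callable[[int, Population], None] | None = None,
) -> tuple[list[GenerationStats], Population]:
    """Execute one GA run; returns (per-generation stats, final population).

    Deterministic given the config seed. `on_generation` is called with the
    1-based generation index and the evaluated population after each
    generation's statistics are recorded — useful for logging or invariant
    checking.
    """
    rng = ensure_rng(config.seed)
    n = config.population_size
    pop = init_population(n, config.peptide_length, rng)
    evals = _evaluate(pop, config.fitness, 1)
    trajectory = [_stats(pop, config.fitness, 1, evals)]
    if on_generation is not None:
        on_generation(1, pop)
    orientation = config.fitness.orientation
    for gen in range(2, config.generations + 1):
        n_parents = n if n % 2 == 0 else n + 1
        parents = select_parents(pop, orientation, n_parents, rng, config.selection)
        children: list[Individual] = []
        for i in range(0, n_parents, 2):
            c1, c2 = crossover(
                parents[i].peptide, parents[i + 1].peptide, rng, config.crossover
            )
            children.append(Individual(mutate(c1, rng, config.mutation)))
            children.append(Individual(mutate(c2, rng, config.mutation)))
        del children[n:]  # odd population size: drop the last pair's second child
        pop = Population(individuals=children, size=n, generation=gen - 1)
        purge_duplicates(pop, rng)
        evals = _evaluate(pop, config.fitness, gen)
        trajectory.append(_stats(pop, config.fitness, gen, evals))
        if on_generation is not None:
            on_generation(gen, pop)
    return trajectory, pop


def median_fitness(trajectory: Sequence[GenerationStats]) -> list[float]:
    """The per-generation median fitness series (even-size populations use
    the mean of the two central values)."""
    if not trajectory:
        raise ValueError("trajectory must be nonempty")
    return [s.median for s in trajectory]


@dataclass
class SweepCell:
    """One run of the benchmark grid; `error` is set if the run failed."""

    run_id: int
    selection: str
    crossover: str
    fitness: str
    mutation: str
    seed: int
    trajectory: list[GenerationStats] = field(default_factory=list)
    final_population: Population | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class SweepResult:
    cells: list[SweepCell]
    generations: int
    population_size: int

    @property
    def total_runs(self) -> int:
        return len(self.cells)

    @property
    def total_evaluations(self) -> int:
        return sum(s.evaluations for c in self.cells if c.ok for s in c.trajectory)

    @property
    def failed_cells(self) -> list[SweepCell]:
        return [c for c in self.cells if not c.ok]


def cell_seed(base_seed: int, index: int) -> int:
    """Deterministic independent per-cell seed derived from the base seed."""
    ss = np.random.SeedSequence([abs(int(base_seed)), index])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def sweep(
    selections: Sequence[SelectionSpec],
    crossovers: Sequence[CrossoverSpec],
    fitnesses: Sequence[FitnessFunction],
    mutations: Sequence[MutationSpec],
    *,
    population_size: int = 100,
    generations: int = 50,
    peptide_length: int = DEFAULT_PEPTIDE_LENGTH,
    base_seed: int = 0,
    progress: Callable[[SweepCell], None] | None = None,
) -> SweepResult:
    """Run every operator combination once, each with an independent seed.

    A failing cell is recorded with its diagnostic and the sweep continues.
    The grid order is fitness-major, then selection, crossover, mutation.
    """
    if not (selections and crossovers and fitnesses and mutations):
        raise ValueError("all operator registries must be nonempty")
    cells: list[SweepCell] = []
    grid = itertools.product(fitnesses, selections, crossovers, mutations)
    for run_id, (fit, sel, cx, mut) in enumerate(grid):
        seed = cell_seed(base_seed, run_id)
        cell = SweepCell(
            run_id=run_id, selection=sel.operator, crossover=cx.operator,
            fitness=fit.name, mutation=mut.operator, seed=seed,
        )
        config = GAConfig(
            fitness=fit, selection=sel, crossover=cx, mutation=mut,
            population_size=population_size, generations=generations,
            peptide_length=peptide_length, seed=seed,
        )
        try:
            cell.trajectory, cell.final_population = run_ga(config)
        except (PepgaError, ValueError) as exc:
            cell.error = f"{type(exc).__name__}: {exc}"
        cells.append(cell)
        if progress is not None:
            progress(cell)
    return SweepResult(cells=cells, generations=generations,
                       population_size=population_size)


def default_registry() -> tuple[
    list[SelectionSpec], list[CrossoverSpec], list[FitnessFunction], list[MutationSpec]
]:
    """The full benchmark registry: 7 selection x 6 crossover x 5 bundled
    scorers x 2 mutation operators (420 combinations)."""
    from .crossover import CROSSOVER_OPERATORS
    from .fitness import bundled_scorers
    from .mutation import MUTATION_OPERATORS
    from .selection import SELECTION_OPERATORS

    return (
        [SelectionSpec(op) for op in SELECTION_OPERATORS],
        [CrossoverSpec(op) for op in CROSSOVER_OPERATORS],
        bundled_scorers(),
        [MutationSpec(op) for op in MUTATION_OPERATORS],
    )


def search_space_years(
    length: int, alphabet_size: int, peptides_per_second: float
) -> float:
    """Years needed to score every possible peptide exhaustively.

    alphabet_size**length / (rate * 60 * 60 * 24 * 365) — the arithmetic that
    motivates a heuristic search: 20^9 nonamers at 10 evaluations per second
    exceed 1,600 years.
    """
    if length < 1 or alphabet_size < 1 or peptides_per_second <= 0:
        raise ValueError("all arguments must be positive")
    return alphabet_size**length / (peptides_per_second * 60 * 60 * 24 * 365)
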