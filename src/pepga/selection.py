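"""Parent-selection operators.

Seven schemes for choosing parents from an evaluated population, spanning
the classic spectrum of selection pressure: fitness-proportional roulette,
linear ranking, binary and q-fold tournaments, truncation ("best percent"),
stochastic universal sampling, and a fitness-blind random control. All
operators work on *oriented* fitness (larger is always better, regardless of
whether the underlying scorer is maximised or minimised) and share one
signature: given a population, return k parents, repetition allowed.

Tie-breaking is everywhere stable in input order, so a population, a seed and
a spec determine the parent list exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .core import Individual, Population, RandomSource
from .errors import DegenerateSelectionError
from .fitness import Orientation, selection_weights


@dataclass
class SelectionSpec:
    """Operator name plus its parameters.

    percent — elite fraction for best_percent (default 10%);
    q — tournaments per individual for q_tournament (default 3);
    s — selection pressure in [1, 2] for linear_rank (default 1.5);
    weight_mode — "raw" fitness-proportional wheel or "rescaled" (min-max
    transformed oriented scores), used by roulette and SUS.
    """

    operator: str
    percent: float = 10.0
    q: int = 3
    s: float = 1.5
    weight_mode: Literal["raw", "rescaled"] = "raw"


def _check_common(pop: Population, k: int) -> None:
    if k < 1:
        raise ValueError(f"number of parents k must be >= 1, got {k}")
    if not pop.individuals:
        raise ValueError("cannot select from an empty population")
    if any(ind.fitness is None for ind in pop.individuals):
        raise ValueError("population must be fully evaluated before selection")


def _oriented(pop: Population, orientation: Orientation) -> np.ndarray:
    f = np.array(pop.fitnesses(), dtype=float)
    return f if orientation == "maximize" else -f


def _fitness_order(pop: Population, orientation: Orientation) -> list[int]:
    """Indices sorted best-first by oriented fitness, ties in input order."""
    ori = _oriented(pop, orientation)
    return sorted(range(len(ori)), key=lambda i: (-ori[i], i))


def roulette_select(
    pop: Population, orientation: Orientation, k: int,
    rng: RandomSource, spec: SelectionSpec,
) -> list[Individual]:
    """Fitness-proportional wheel: P(i) = w_i / sum(w), draws independent."""
    _check_common(pop, k)
    w = selection_weights(pop.fitnesses(), orientation, mode=spec.weight_mode)
    p = w / w.sum()
    idx = rng.choice(len(p), size=k, p=p)
    return [pop.individuals[i] for i in idx]


def linear_rank_select(
    pop: Population, orientation: Orientation, k: int,
    rng: RandomSource, spec: SelectionSpec,
) -> list[Individual]:
    """Linear ranking with pressure s in [1, 2].

    With ranks i = 1 (best) .. N (worst):
        P(rank i) = (1/N) * (s - 2*(s-1)*(i-1)/(N-1))
    s = 1 gives uniform selection, s = 2 the steepest linear ramp (the worst
    rank gets probability 0).
    """
    _check_common(pop, k)
    s = spec.s
    if not 1.0 <= s <= 2.0:
        raise ValueError(f"linear-rank pressure s must be in [1, 2], got {s}")
    n = len(pop.individuals)
    if n == 1:
        return [pop.individuals[0]] * k
    order = _fitness_order(pop, orientation)
    ranks = np.arange(1, n + 1)
    probs = (s - 2.0 * (s - 1.0) * (ranks - 1) / (n - 1)) / n
    idx = rng.choice(n, size=k, p=probs / probs.sum())
    return [pop.individuals[order[i]] for i in idx]


def binary_tournament_select(
    pop: Population, orientation: Orientation, k: int,
    rng: RandomSource, spec: SelectionSpec,
) -> list[Individual]:
    """Per draw, two uniform picks (with replacement); the strictly fitter
    wins deterministically, exact ties are settled by a fair coin."""
    _check_common(pop, k)
    n = len(pop.individuals)
    ori = _oriented(pop, orientation)
    a = rng.integers(0, n, size=k)
    b = rng.integers(0, n, size=k)
    coin = rng.random(k) < 0.5
    out = []
    for i in range(k):
        ia, ib = a[i], b[i]
        if ori[ia] > ori[ib]:
            win = ia
        elif ori[ib] > ori[ia]:
            win = ib
        else:
            win = ia if coin[i] else ib
        out.append(pop.individuals[win])
    return out


def random_select(
    pop: Population, orientation: Orientation, k: int,
    rng: RandomSource, spec: SelectionSpec,
) -> list[Individual]:
    """Uniform, fitness-blind selection — the negative control."""
    _check_common(pop, k)
    idx = rng.integers(0, len(pop.individuals), size=k)
    return [pop.individuals[i] for i in idx]


def best_percent_select(
    pop: Population, orientation: Orientation, k: int,
    rng: RandomSource, spec: SelectionSpec,
) -> list[Individual]:
    """Truncation selection: the top ceil(N * percent / 100) individuals are
    cycled in fitness order until k parent slots are filled. Deterministic."""
    _check_common(pop, k)
    if not 0.0 < spec.percent <= 100.0:
        raise ValueError(f"percent must be in (0, 100], got {spec.percent}")
    n = len(pop.individuals)
    m = math.ceil(n * spec.percent / 100.0)
    elite = _fitness_order(pop, orientation)[:m]
    return [pop.individuals[elite[i % m]] for i in range(k)]


def q_tournament_select(
    pop: Population, orientation: Orientation, k: int,
    rng: RandomSource, spec: SelectionSpec,
) -> list[Individual]:
    """Every individual plays q tournaments, each against an opponent drawn
    uniformly from the rest of the population (with replacement across
    tournaments); a strict win counts 1, a fitness tie 0.5. Individuals are
    ranked by victories (ties by oriented fitness, then input order) and the
    top k are returned, cycling if k exceeds the population size. The best
    individual can never lose a tournament, so it always heads the ranking."""
    _check_common(pop, k)
    if spec.q < 1:
        raise ValueError(f"q must be >= 1, got {spec.q}")
    n = len(pop.individuals)
    if n == 1:
        return [pop.individuals[0]] * k
    ori = _oriented(pop, orientation)
    opponents = rng.integers(0, n - 1, size=(n, spec.q))
    opponents += opponents >= np.arange(n)[:, None]  # skip self
    opp_fit = ori[opponents]
    mine = ori[:, None]
    victories = (mine > opp_fit).sum(axis=1) + 0.5 * (mine == opp_fit).sum(axis=1)
    order = sorted(range(n), key=lambda i: (-victories[i], -ori[i], i))
    return [pop.individuals[order[i % n]] for i in range(k)]


def sus_select(
    pop: Population, orientation: Orientation, k: int,
    rng: RandomSource, spec: SelectionSpec,
) -> list[Individual]:
    """Stochastic universal sampling: one spin of the wheel with k equally
    spaced pointers and a single uniform offset in [0, sum(w)/k). Each
    individual receives floor(k*p_i) or ceil(k*p_i) copies."""
    _check_common(pop, k)
    w = selection_weights(pop.fitnesses(), orientation, mode=spec.weight_mode)
    total = float(w.sum())
    if total <= 0:
        raise DegenerateSelectionError("zero total selection weight")
    step = total / k
    start = rng.uniform(0.0, step)
    pointers = start + step * np.arange(k)
    cum = np.cumsum(w)
    idx = np.searchsorted(cum, pointers, side="right")
    idx = np.minimum(idx, len(w) - 1)  # guard float round-off at the wheel end
    return [pop.individuals[i] for i in idx]


SELECTION_OPERATORS: dict[str, Callable[..., list[Individual]]] = {
    "roulette": roulette_select,
    "linear_rank": linear_rank_select,
    "binary_tournament": binary_tournament_select,
    "random": random_select,
    "best_percent": best_percent_select,
    "q_tournament": q_tournament_select,
    "sus": sus_select,
}


def select_parents(
    pop: Population, orientation: Orientation, k: int,
    rng: RandomSource, spec: SelectionSpec,
) -> list[Individual]:
    """Dispatch to the operator named in `spec`."""
    try:
        fn = SELECTION_OPERATORS[spec.operator]
    except KeyError:
        raise ValueError(
            f"unknown selection operator {spec.operator!r}; "
            f"valid: {', '.join(sorted(SELECTION_OPERATORS))}"
        ) from None
    return fn(pop, orientation, k, rng, spec)
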