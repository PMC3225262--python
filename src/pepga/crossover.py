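"""Recombination operators.

Each operator maps a pair of equal-length parent peptides to two children.
All six share one structural guarantee, *allele conservation*: at every
position, the two children's residues are exactly the two parents' residues
at that position (possibly swapped). Crossover therefore never invents a
residue; only mutation introduces new alleles.

Cut-point convention: a cut at c (1-based, c in 1..L-1) separates positions
1..c from c+1..L, so no cut produces an empty segment. Optional keyword
arguments (`cut`, `cuts`, `r`, `perm`, `draws`) force the random choices,
which keeps every operator unit-testable against hand-worked examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

from .core import RandomSource


@dataclass
class CrossoverSpec:
    """Operator name plus parameters (uniform crossover's swap threshold)."""

    operator: str
    threshold: float = 0.5


def _check(p1: str, p2: str) -> int:
    if len(p1) != len(p2):
        raise ValueError(f"parent lengths differ: {len(p1)} vs {len(p2)}")
    if len(p1) < 2:
        raise ValueError("crossover requires peptide length >= 2")
    return len(p1)


def _exchange_at_cuts(p1: str, p2: str, cuts: Sequence[int]) -> tuple[str, str]:
    """Exchange alternating segments, starting with the second segment.

    Segments are delimited by the sorted cuts; the first segment stays with
    its own parent, the second is swapped, and so on.
    """
    length = len(p1)
    bounds = [0, *sorted(cuts), length]
    c1, c2 = [], []
    for seg, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        if seg % 2 == 0:
            c1.append(p1[lo:hi])
            c2.append(p2[lo:hi])
        else:
            c1.append(p2[lo:hi])
            c2.append(p1[lo:hi])
    return "".join(c1), "".join(c2)


def _draw_cuts(length: int, r: int, rng: RandomSource) -> list[int]:
    return sorted(int(c) for c in rng.choice(length - 1, size=r, replace=False) + 1)


def single_point_cross(
    p1: str, p2: str, rng: RandomSource | None = None, *, cut: int | None = None
) -> tuple[str, str]:
    """One cut, uniform over 1..L-1; tails exchanged."""
    length = _check(p1, p2)
    if cut is None:
        cut = int(rng.integers(1, length))
    if not 1 <= cut <= length - 1:
        raise ValueError(f"cut must be in 1..{length - 1}, got {cut}")
    return _exchange_at_cuts(p1, p2, [cut])


def double_point_cross(
    p1: str, p2: str, rng: RandomSource | None = None,
    *, cuts: tuple[int, int] | None = None,
) -> tuple[str, str]:
    """Two distinct cuts; the middle segment is exchanged."""
    length = _check(p1, p2)
    if length < 3:
        raise ValueError("double-point crossover requires length >= 3 (two distinct cuts)")
    if cuts is None:
        cuts = tuple(_draw_cuts(length, 2, rng))
    lo, hi = sorted(cuts)
    if not (1 <= lo < hi <= length - 1):
        raise ValueError(f"cuts must be distinct and in 1..{length - 1}, got {cuts}")
    return _exchange_at_cuts(p1, p2, [lo, hi])


def distance_bisector_cross(
    p1: str, p2: str, rng: RandomSource | None = None
) -> tuple[str, str]:
    """Deterministic cut after position ceil(L/2) — for nonamers, after
    position 5, the middle of the MHC class I binding groove."""
    length = _check(p1, p2)
    return _exchange_at_cuts(p1, p2, [math.ceil(length / 2)])


def multi_point_cross(
    p1: str, p2: str, rng: RandomSource | None = None,
    *, r: int | None = None, cuts: Sequence[int] | None = None,
) -> tuple[str, str]:
    """r cuts at r distinct random positions, r itself uniform over 1..L-1;
    segments exchanged alternately starting with the second."""
    length = _check(p1, p2)
    if cuts is not None:
        cuts = sorted(int(c) for c in cuts)
        if len(set(cuts)) != len(cuts) or not all(1 <= c <= length - 1 for c in cuts):
            raise ValueError(f"cuts must be distinct and in 1..{length - 1}, got {cuts}")
    else:
        if r is None:
            r = int(rng.integers(1, length))
        if not 1 <= r <= length - 1:
            raise ValueError(f"r must be in 1..{length - 1}, got {r}")
        cuts = _draw_cuts(length, r, rng)
    return _exchange_at_cuts(p1, p2, cuts)


def uniform_cross(
    p1: str, p2: str, rng: RandomSource | None = None,
    *, threshold: float = 0.5, draws: Sequence[float] | None = None,
) -> tuple[str, str]:
    """Independent uniform(0,1) draw per position; a draw above the threshold
    swaps that position's residues between the children."""
    length = _check(p1, p2)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if draws is None:
        draws = rng.random(length)
    c1 = list(p1)
    c2 = list(p2)
    for i, u in enumerate(draws):
        if u > threshold:
            c1[i], c2[i] = c2[i], c1[i]
    return "".join(c1), "".join(c2)


def shuffle_cross(
    p1: str, p2: str, rng: RandomSource | None = None,
    *, perm: Sequence[int] | None = None, cuts: tuple[int, int] | None = None,
) -> tuple[str, str]:
    """Double-point crossover in a shuffled coordinate system.

    One random permutation is applied to both parents (sharing it is what
    keeps alleles conserved positionwise), a two-point crossover is performed
    in shuffled space, and the inverse permutation restores the original
    coordinates. Net effect: a random positional subset is exchanged, freeing
    the two-point operator from its contiguity bias.
    """
    length = _check(p1, p2)
    if perm is None:
        perm = rng.permutation(length)
    perm = [int(i) for i in perm]
    if sorted(perm) != list(range(length)):
        raise ValueError("perm must be a permutation of 0..L-1")
    s1 = "".join(p1[j] for j in perm)
    s2 = "".join(p2[j] for j in perm)
    sc1, sc2 = double_point_cross(s1, s2, rng, cuts=cuts)
    c1 = [""] * length
    c2 = [""] * length
    for i, j in enumerate(perm):
        c1[j] = sc1[i]
        c2[j] = sc2[i]
    return "".join(c1), "".join(c2)


CROSSOVER_OPERATORS: dict[str, Callable[..., tuple[str, str]]] = {
    "single_point": single_point_cross,
    "double_point": double_point_cross,
    "distance_bisector": distance_bisector_cross,
    "multi_point": multi_point_cross,
    "uniform": uniform_cross,
    "shuffle": shuffle_cross,
}


def crossover(
    p1: str, p2: str, rng: RandomSource, spec: CrossoverSpec
) -> tuple[str, str]:
    """Dispatch to the operator named in `spec`."""
    try:
        fn = CROSSOVER_OPERATORS[spec.operator]
    except KeyError:
        raise ValueError(
            f"unknown crossover operator {spec.operator!r}; "
            f"valid: {', '.join(sorted(CROSSOVER_OPERATORS))}"
        ) from None
    if spec.operator == "uniform":
        return fn(p1, p2, rng, threshold=spec.threshold)
    return fn(p1, p2, rng)
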