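"""Post-run analyses of optimised peptide sets.

Given the best individuals of a run or sweep, this module computes the
standard sequence-level summaries: consensus sequences (positionwise modal
residue), position frequency matrices with per-column information content
(the numbers behind a sequence logo), additive Van der Waals volumes (how
fully a peptide fills the MHC binding groove, in cubic aangstroems), and
Levenshtein edit distances against a reference peptide set (e.g. a download
of experimentally measured binders) to judge whether the optimiser proposes
novel sequences.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, validate_peptide
from .engine import GenerationStats, SweepResult


def _validated_equal_length(peptides: Sequence[str]) -> list[str]:
    peps = [validate_peptide(p) for p in peptides]
    if not peps:
        raise ValueError("peptide list must be nonempty")
    if len({len(p) for p in peps}) != 1:
        raise ValueError("peptides must all have equal length")
    return peps


@dataclass
class PositionFrequencyMatrix:
    """Columnwise residue frequencies of an aligned peptide set."""

    frequencies: pd.DataFrame  # index = positions 1..L, columns = residues
    sample_size: int

    @property
    def length(self) -> int:
        return len(self.frequencies)

    def consensus(self) -> str:
        """Positionwise argmax; ties resolved alphabetically (columns are in
        alphabetical order, idxmax keeps the first)."""
        return "".join(self.frequencies.idxmax(axis=1))

    def information_content(self, small_sample_correction: bool = False) -> np.ndarray:
        """Per-position information content in bits: log2(20) minus the
        Shannon entropy of the column (the height of a logo stack). The
        optional correction subtracts the small-sample bias term
        (20-1)/(2*ln2*n)."""
        f = self.frequencies.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(f > 0, f * np.log2(f), 0.0)
        entropy = -plogp.sum(axis=1)
        ic = np.log2(len(self.frequencies.columns)) - entropy
        if small_sample_correction:
            ic -= (len(self.frequencies.columns) - 1) / (
                2 * np.log(2) * self.sample_size
            )
        return ic

    def to_tsv(self, path: str | Path) -> None:
        self.frequencies.rename_axis("pos").to_csv(path, sep="\t")


def position_frequency_matrix(peptides: Sequence[str]) -> PositionFrequencyMatrix:
    peps = _validated_equal_length(peptides)
    length = len(peps[0])
    counts = np.zeros((length, len(AMINO_ACIDS)))
    for pep in peps:
        for i, aa in enumerate(pep):
            counts[i, AMINO_ACIDS.index(aa)] += 1
    freqs = pd.DataFrame(
        counts / len(peps),
        index=pd.RangeIndex(1, length + 1),
        columns=list(AMINO_ACIDS),
    )
    return PositionFrequencyMatrix(frequencies=freqs, sample_size=len(peps))


def consensus_sequence(peptides: Sequence[str]) -> str:
    """Positionwise most frequent residue; ties broken alphabetically."""
    peps = _validated_equal_length(peptides)
    out = []
    for i in range(len(peps[0])):
        counts = Counter(p[i] for p in peps)
        best = max(sorted(counts), key=lambda aa: counts[aa])
        out.append(best)
    return "".join(out)


def best_individuals(
    result: SweepResult | Sequence[GenerationStats],
    generation: int,
    group_by_fitness: bool = False,
) -> list[str] | dict[str, list[str]]:
    """Best peptide of the requested generation, one per run.

    Accepts a sweep result (failed cells skipped) or a single run trajectory.
    With `group_by_fitness`, peptides are grouped by scoring-function name —
    the input of a per-scorer sequence logo.
    """
    if isinstance(result, SweepResult):
        cells = [c for c in result.cells if c.ok]
        if not cells:
            raise ValueError("sweep contains no successful runs")
        if any(generation < 1 or generation > len(c.trajectory) for c in cells):
            raise ValueError(f"generation {generation} out of range")
        if group_by_fitness:
            grouped: dict[str, list[str]] = {}
            for c in cells:
                grouped.setdefault(c.fitness, []).append(
                    c.trajectory[generation - 1].best_peptide
                )
            return grouped
        return [c.trajectory[generation - 1].best_peptide for c in cells]
    trajectory = list(result)
    if generation < 1 or generation > len(trajectory):
        raise ValueError(f"generation {generation} out of range")
    return [trajectory[generation - 1].best_peptide]


def load_volume_table(path: str | Path | None = None) -> dict[str, float]:
    """Per-residue Van der Waals volumes (cubic aangstroems)."""
    if path is None:
        path = Path(str(resources.files("pepga").joinpath("data", "vdw_volumes.tsv")))
    table: dict[str, float] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[row["residue"]] = float(row["volume_A3"])
    missing = set(AMINO_ACIDS) - set(table)
    if missing:
        raise ValueError(f"volume table missing residues: {sorted(missing)}")
    if any(v <= 0 for v in table.values()):
        raise ValueError("volumes must be positive")
    return table


_DEFAULT_VOLUMES: dict[str, float] | None = None


def vdw_volume(peptide: str, table: dict[str, float] | None = None) -> float:
    """Sum of per-residue Van der Waals volumes, in cubic aangstroems."""
    global _DEFAULT_VOLUMES
    if table is None:
        if _DEFAULT_VOLUMES is None:
            _DEFAULT_VOLUMES = load_volume_table()
        table = _DEFAULT_VOLUMES
    pep = validate_peptide(peptide)
    try:
        return float(sum(table[aa] for aa in pep))
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} missing from volume table") from exc


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    a, b = str(a), str(b)
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])


@dataclass
class ReferenceComparison:
    """Minimum edit distance of each query peptide to a reference set."""

    min_distances: list[int]
    histogram: dict[int, int]
    exact_matches: int

    @property
    def n_queries(self) -> int:
        return len(self.min_distances)


def compare_to_reference(
    peptides: Sequence[str], reference: Sequence[str]
) -> ReferenceComparison:
    """For each query, the minimum Levenshtein distance to any reference
    peptide, plus the histogram of those minima and the exact-match count."""
    if not reference:
        raise ValueError("reference set must be nonempty")
    queries = [validate_peptide(p) for p in peptides]
    refs = [validate_peptide(r) for r in reference]
    minima = [min(levenshtein(q, r) for r in refs) for q in queries]
    hist = dict(sorted(Counter(minima).items()))
    return ReferenceComparison(
        min_distances=minima,
        histogram=hist,
        exact_matches=sum(1 for m in minima if m == 0),
    )
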