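"""Offspring mutation operators.

Two point-mutation models act independently on each peptide position with a
configurable per-position probability (default 3%):

* amino-acid class mutation — the residue is replaced by one drawn uniformly
  from the three chemical classes it does NOT belong to (unpolar, polar,
  basic, acidic), so a mutation always changes the residue's class;
* nucleobase mutation — the mutation happens at the DNA level: a codon for
  the current residue is chosen uniformly among its synonymous codons, one of
  its three bases is substituted by a random different base (redrawn until
  the result is not a stop codon), and the mutated codon is translated back.
  Silent mutations are possible, so the residue may stay unchanged.

The genetic code is the standard table; the class partition ships as an
editable TSV fixture.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable

from Bio.Data import CodonTable

from .core import AMINO_ACIDS, RandomSource, validate_peptide

NUCLEOTIDES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, standard genetic code (stop codons excluded)
GENETIC_CODE: dict[str, str] = dict(_standard.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
#: amino acid -> sorted tuple of synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in GENETIC_CODE.items() if a == aa))
    for aa in AMINO_ACIDS
}


def load_class_table(path: str | Path | None = None) -> dict[str, str]:
    """Read the residue->class TSV; returns {class_name: residues}."""
    if path is None:
        path = Path(str(resources.files("pepga").joinpath("data", "aa_classes.tsv")))
    classes: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            classes[row["class"]] = classes.get(row["class"], "") + row["residue"]
    residues = "".join(classes.values())
    if sorted(residues) != sorted(AMINO_ACIDS):
        raise ValueError("class table must partition the 20-residue alphabet")
    return classes


DEFAULT_CLASSES = load_class_table()

#: residue -> string of all residues belonging to a different class
_OTHER_CLASS: dict[str, str] = {}
for _cls, _members in DEFAULT_CLASSES.items():
    _others = "".join(m for c, ms in DEFAULT_CLASSES.items() if c != _cls for m in ms)
    for _aa in _members:
        _OTHER_CLASS[_aa] = _others


@dataclass
class MutationSpec:
    operator: str
    rate: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"mutation rate must be in [0, 1], got {self.rate}")


def residue_class(aa: str, classes: dict[str, str] | None = None) -> str:
    for cls, members in (classes or DEFAULT_CLASSES).items():
        if aa in members:
            return cls
    raise ValueError(f"residue {aa!r} not in class table")


def aa_class_mutate(
    peptide: str, rng: RandomSource, rate: float = 0.03,
    classes: dict[str, str] | None = None,
) -> str:
    """Class-changing point mutation at each position with probability `rate`."""
    pep = validate_peptide(peptide)
    if classes is None:
        other = _OTHER_CLASS
    else:
        other = {}
        for cls, members in classes.items():
            pool = "".join(m for c, ms in classes.items() if c != cls for m in ms)
            for aa in members:
                other[aa] = pool
    mask = rng.random(len(pep)) < rate
    out = list(pep)
    for i, hit in enumerate(mask):
        if hit:
            pool = other[out[i]]
            out[i] = pool[rng.integers(len(pool))]
    return "".join(out)


def _mutate_codon(codon: str, rng: RandomSource) -> str:
    """Substitute one base of `codon`, rejection-resampling stop codons."""
    while True:
        pos = int(rng.integers(3))
        alternatives = [b for b in NUCLEOTIDES if b != codon[pos]]
        base = alternatives[rng.integers(3)]
        candidate = codon[:pos] + base + codon[pos + 1:]
        if candidate not in STOP_CODONS:
            return candidate


def nucleobase_mutate(peptide: str, rng: RandomSource, rate: float = 0.03) -> str:
    """Codon-level point mutation at each position with probability `rate`.

    A synonymous codon for the residue is drawn uniformly, one base is
    substituted (stop codons avoided by redrawing the base substitution while
    keeping the codon), and the result is translated back. The residue may be
    unchanged if the substitution is silent.
    """
    pep = validate_peptide(peptide)
    mask = rng.random(len(pep)) < rate
    out = list(pep)
    for i, hit in enumerate(mask):
        if hit:
            codons = AA_TO_CODONS[out[i]]
            codon = codons[rng.integers(len(codons))]
            out[i] = GENETIC_CODE[_mutate_codon(codon, rng)]
    return "".join(out)


def single_base_neighbors(aa: str) -> set[str]:
    """Amino acids reachable from `aa` by one non-stop base substitution in
    any of its codons (the residue itself included when a silent or
    synonym-crossing change exists)."""
    reachable: set[str] = set()
    for codon in AA_TO_CODONS[aa]:
        for pos in range(3):
            for base in NUCLEOTIDES:
                if base == codon[pos]:
                    continue
                cand = codon[:pos] + base + codon[pos + 1:]
                if cand not in STOP_CODONS:
                    reachable.add(GENETIC_CODE[cand])
    return reachable


MUTATION_OPERATORS: dict[str, Callable[..., str]] = {
    "aa_class": aa_class_mutate,
    "nucleobase": nucleobase_mutate,
}


def mutate(peptide: str, rng: RandomSource, spec: MutationSpec) -> str:
    """Dispatch to the operator named in `spec`."""
    try:
        fn = MUTATION_OPERATORS[spec.operator]
    except KeyError:
        raise ValueError(
            f"unknown mutation operator {spec.operator!r}; "
            f"valid: {', '.join(sorted(MUTATION_OPERATORS))}"
        ) from None
    return fn(peptide, rng, rate=spec.rate)
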