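"""Fitness functions for peptide-MHC binding optimisation.

A fitness function maps a peptide to a real score and declares an
optimisation orientation: binding predictors that report e.g. a SYFPEITHI-like
score are maximised, while IC50-style predictors are minimised (lower IC50 =
stronger binding). Selection operators never see raw scores directly; they
consume oriented values or nonnegative selection weights derived here, so one
engine serves both orientations.

Three families of scorers are provided:

* additive position scoring matrices (an L x 20 weight table summed over
  positions), the classic sequence-based model behind PSSM predictors;
* a Hamming-peak toy landscape with a known global optimum, used to verify
  convergence behaviour analytically;
* an adapter that shells out to an arbitrary external prediction command,
  so published predictors can be plugged in unchanged.

Five bundled matrices (one of them orientation="minimize", playing the role
of an IC50-scale predictor) form the default registry for the operator sweep.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from .core import AMINO_ACIDS, validate_peptide
from .errors import DegenerateSelectionError, ExternalScorerError

Orientation = Literal["maximize", "minimize"]


@dataclass
class FitnessFunction:
    """A named scorer with an optimisation orientation.

    `score` must be deterministic for a fixed peptide. `score_batch`, when
    set, evaluates many peptides in one call (used by the external-command
    adapter to avoid one process per peptide).
    """

    name: str
    orientation: Orientation
    score: Callable[[str], float]
    score_batch: Callable[[Sequence[str]], list[float]] | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("maximize", "minimize"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def oriented(self, value: float) -> float:
        """Map a raw score to a 'larger is better' scale."""
        return value if self.orientation == "maximize" else -value

    def __call__(self, peptide: str) -> float:
        return self.score(peptide)


@dataclass
class ScoringMatrix:
    """Additive per-position scoring table (L positions x 20 residues)."""

    weights: np.ndarray  # shape (length, 20), columns in AMINO_ACIDS order
    residues: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != len(self.residues):
            raise ValueError("weights must be an (L, n_residues) table")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("scoring matrix weights must be finite")
        self._col = {aa: j for j, aa in enumerate(self.residues)}

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    def __add__(self, other: "ScoringMatrix") -> "ScoringMatrix":
        if self.length != other.length or self.residues != other.residues:
            raise ValueError("can only add matrices of identical shape")
        return ScoringMatrix(self.weights + other.weights, self.residues)

    def score(self, peptide: str) -> float:
        return matrix_score(peptide, self)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoringMatrix":
        """Read the TSV dialect: header 'pos' + residue letters, one row per
        position."""
        lines = Path(path).read_text().strip().splitlines()
        header = lines[0].split("\t")
        if header[0] != "pos":
            raise ValueError(f"{path}: first header cell must be 'pos'")
        residues = "".join(header[1:])
        rows = [list(map(float, ln.split("\t")[1:])) for ln in lines[1:]]
        return cls(np.array(rows), residues)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pos\t" + "\t".join(self.residues) + "\n")
            for i, row in enumerate(self.weights, start=1):
                fh.write(str(i) + "\t" + "\t".join(f"{w:g}" for w in row) + "\n")


def matrix_score(peptide: str, matrix: ScoringMatrix) -> float:
    """Sum of per-position residue weights."""
    pep = validate_peptide(peptide)
    if len(pep) != matrix.length:
        raise ValueError(
            f"peptide length {len(pep)} != matrix length {matrix.length}"
        )
    total = 0.0
    for i, aa in enumerate(pep):
        j = matrix._col.get(aa)
        if j is None:
            raise ValueError(f"residue {aa!r} not covered by scoring matrix")
        total += matrix.weights[i, j]
    return total


def hamming_peak_score(peptide: str, target: str) -> float:
    """L minus the Hamming distance to `target`.

    A smooth single-peak landscape: the unique global optimum is `target`
    itself with score L. Used to test engine convergence against a known
    answer.
    """
    pep = validate_peptide(peptide)
    tgt = validate_peptide(target)
    if len(pep) != len(tgt):
        raise ValueError("peptide and target lengths differ")
    return float(sum(a == b for a, b in zip(pep, tgt)))


def hamming_peak_fitness(target: str, name: str = "hamming_peak") -> FitnessFunction:
    tgt = validate_peptide(target)
    return FitnessFunction(name=name, orientation="maximize",
                           score=lambda p: hamming_peak_score(p, tgt))


def selection_weights(
    scores: Sequence[float],
    orientation: Orientation,
    mode: Literal["raw", "rescaled"] = "raw",
) -> np.ndarray:
    """Nonnegative selection weights from raw fitness scores.

    In "raw" mode the weights are fitness-proportional in the spirit of a
    plain roulette wheel: for maximisation the raw scores are used directly
    (shifted up only if negatives occur); for minimisation each score s is
    reflected to (max + min) - s, so that smaller-is-better maps to
    larger-is-better while keeping the original (possibly weak) spread. On an
    IC50-like scale spanning [0, ~50,000] this reflection deliberately leaves
    little contrast between strong binders (<500 nM) and mediocre ones, which
    is exactly the weak selection pressure a naive wheel exerts there.

    "rescaled" mode replaces each score by its (average, tie-sharing) rank on
    the oriented scale, so the wheel sees a flat distribution with full
    contrast regardless of how the raw scores cluster — the distribution
    transformation that fixes the wheel on IC50 scores.

    A tiny epsilon (1e-9 of the score range) keeps shifted weights strictly
    positive; if every weight still collapses to zero a
    DegenerateSelectionError is raised.
    """
    if len(scores) == 0:
        raise ValueError("scores must be nonempty")
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    rng_span = float(s.max() - s.min())
    eps = 1e-9 * (rng_span if rng_span > 0 else 1.0)
    if mode == "rescaled":
        oriented = s if orientation == "maximize" else -s
        w = _average_ranks(oriented)
    elif mode == "raw":
        if orientation == "maximize":
            w = s.copy()
            if w.min() < 0:
                w = w - w.min() + eps
        else:
            w = (s.max() + s.min()) - s
            if w.min() < 0:
                w = w - w.min() + eps
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    if w.sum() <= 0:
        raise DegenerateSelectionError(
            "all selection weights are zero; fitness-proportional selection "
            "is undefined for this population"
        )
    return w


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1 (worst) .. n (best); ties share the mean of their positions."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def external_scorer(command_template: str, peptides: Sequence[str]) -> list[float]:
    """Run an external prediction command on a batch of peptides.

    The template must contain an ``{input}`` placeholder, replaced by the
    path of a temporary plain-text file holding one peptide per line. The
    command must print one real score per input line to stdout, in input
    order. Nonzero exit status or a line-count mismatch raises
    ExternalScorerError carrying the program's diagnostics.
    """
    if "{input}" not in command_template:
        raise ValueError("command template must contain an {input} placeholder")
    peps = [validate_peptide(p) for p in peptides]
    with tempfile.NamedTemporaryFile("w", suffix=".txt", delete=False) as fh:
        fh.write("\n".join(peps) + "\n")
        tmp = fh.name
    try:
        proc = subprocess.run(
            command_template.replace("{input}", tmp),
            shell=True, capture_output=True, text=True,
        )
    finally:
        Path(tmp).unlink(missing_ok=True)
    if proc.returncode != 0:
        raise ExternalScorerError(
            f"scorer exited with status {proc.returncode}: {proc.stderr.strip()}"
        )
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    if len(lines) != len(peps):
        raise ExternalScorerError(
            f"scorer returned {len(lines)} scores for {len(peps)} peptides"
        )
    try:
        return [float(ln.strip()) for ln in lines]
    except ValueError as exc:
        raise ExternalScorerError(f"unparseable scorer output: {exc}") from exc


def external_fitness(
    name: str, command_template: str, orientation: Orientation
) -> FitnessFunction:
    """Wrap an external prediction command as a FitnessFunction."""

    def _batch(peptides: Sequence[str]) -> list[float]:
        return external_scorer(command_template, peptides)

    return FitnessFunction(
        name=name,
        orientation=orientation,
        score=lambda p: external_scorer(command_template, [p])[0],
        score_batch=_batch,
    )


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("pepga").joinpath("data", filename)))


#: names and orientations of the bundled stand-in scorers. `ic50_surrogate`
#: runs on an IC50-like 0-50,000 scale and is minimised; the others are
#: maximised PSSM-style scorers on assorted scales (pssm_c contains negative
#: weights and exercises the nonnegativity shift).
BUNDLED_SCORERS: dict[str, Orientation] = {
    "ic50_surrogate": "minimize",
    "pssm_a": "maximize",
    "pssm_b": "maximize",
    "pssm_c": "maximize",
    "pssm_d": "maximize",
}


def load_bundled_matrix(name: str) -> ScoringMatrix:
    if name not in BUNDLED_SCORERS:
        raise KeyError(
            f"unknown bundled scorer {name!r}; available: {sorted(BUNDLED_SCORERS)}"
        )
    return ScoringMatrix.from_tsv(_data_path(f"matrix_{name}.tsv"))


def bundled_scorers() -> list[FitnessFunction]:
    """The default registry of five bundled additive scorers."""
    out = []
    for name, orientation in BUNDLED_SCORERS.items():
        m = load_bundled_matrix(name)
        out.append(FitnessFunction(name=name, orientation=orientation, score=m.score))
    return out
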