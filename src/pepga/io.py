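"""File round-tripping and run configuration.

Peptide sets travel as FASTA (or one-peptide-per-line text), trajectories and
sweep grids as TSV, run configurations as YAML, and every run directory gets
a JSON manifest carrying the resolved configuration, tool version and seed —
enough to replay the run bit-exactly.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import DEFAULT_PEPTIDE_LENGTH, validate_peptide
from .crossover import CROSSOVER_OPERATORS, CrossoverSpec
from .engine import GAConfig, GenerationStats, SweepResult
from .fitness import (
    BUNDLED_SCORERS,
    FitnessFunction,
    ScoringMatrix,
    bundled_scorers,
    external_fitness,
    hamming_peak_fitness,
    load_bundled_matrix,
)
from .mutation import MUTATION_OPERATORS, MutationSpec
from .selection import SELECTION_OPERATORS, SelectionSpec


def read_peptides_fasta(path: str | Path, length: int | None = None) -> list[str]:
    """Read a FASTA peptide set; sequences are uppercased and validated."""
    return [
        validate_peptide(str(rec.seq), length)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_peptides_fasta(
    path: str | Path, peptides: Sequence[str], ids: Sequence[str] | None = None
) -> None:
    if ids is None:
        ids = [f"peptide_{i + 1}" for i in range(len(peptides))]
    records = [
        SeqRecord(Seq(validate_peptide(p)), id=name, description="")
        for p, name in zip(peptides, ids)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_peptide_list(path: str | Path, length: int | None = None) -> list[str]:
    """One peptide per line, blank lines ignored."""
    return [
        validate_peptide(ln.strip(), length)
        for ln in Path(path).read_text().splitlines()
        if ln.strip()
    ]


def resolve_fitness(conf: dict[str, Any] | str) -> FitnessFunction:
    """Build a FitnessFunction from its config mapping.

    Accepted forms:
      "pssm_a"                                   — a bundled scorer by name
      {name: pssm_a}                             — same
      {matrix: path.tsv, orientation: maximize}  — additive matrix from file
      {command: "...", orientation: minimize}    — external scorer adapter
      {target: LLDVTAAGL}                        — Hamming-peak toy landscape
    """
    if isinstance(conf, str):
        conf = {"name": conf}
    if "matrix" in conf:
        m = ScoringMatrix.from_tsv(conf["matrix"])
        return FitnessFunction(
            name=conf.get("name", Path(conf["matrix"]).stem),
            orientation=conf.get("orientation", "maximize"),
            score=m.score,
        )
    if "command" in conf:
        return external_fitness(
            conf.get("name", "external"), conf["command"],
            conf.get("orientation", "maximize"),
        )
    if "target" in conf:
        return hamming_peak_fitness(conf["target"], conf.get("name", "hamming_peak"))
    name = conf["name"]
    if name not in BUNDLED_SCORERS:
        raise ValueError(
            f"unknown fitness function {name!r}; bundled: {sorted(BUNDLED_SCORERS)}"
        )
    m = load_bundled_matrix(name)
    return FitnessFunction(name=name, orientation=BUNDLED_SCORERS[name], score=m.score)


def _selection_spec(conf: dict[str, Any] | str) -> SelectionSpec:
    if isinstance(conf, str):
        conf = {"operator": conf}
    op = conf.get("operator")
    if op not in SELECTION_OPERATORS:
        raise ValueError(
            f"unknown selection operator {op!r}; "
            f"valid: {', '.join(sorted(SELECTION_OPERATORS))}"
        )
    return SelectionSpec(**conf)


def _crossover_spec(conf: dict[str, Any] | str) -> CrossoverSpec:
    if isinstance(conf, str):
        conf = {"operator": conf}
    op = conf.get("operator")
    if op not in CROSSOVER_OPERATORS:
        raise ValueError(
            f"unknown crossover operator {op!r}; "
            f"valid: {', '.join(sorted(CROSSOVER_OPERATORS))}"
        )
    return CrossoverSpec(**conf)


def _mutation_spec(conf: dict[str, Any] | str) -> MutationSpec:
    if isinstance(conf, str):
        conf = {"operator": conf}
    op = conf.get("operator")
    if op not in MUTATION_OPERATORS:
        raise ValueError(
            f"unknown mutation operator {op!r}; "
            f"valid: {', '.join(sorted(MUTATION_OPERATORS))}"
        )
    return MutationSpec(**conf)


def load_run_config(path: str | Path, **overrides: Any) -> tuple[GAConfig, dict]:
    """Read a YAML run configuration; keyword overrides win over file values.

    Returns the GAConfig plus the resolved raw mapping (for the manifest).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    config = GAConfig(
        fitness=resolve_fitness(raw.get("fitness", "pssm_a")),
        selection=_selection_spec(raw.get("selection", "binary_tournament")),
        crossover=_crossover_spec(raw.get("crossover", "single_point")),
        mutation=_mutation_spec(raw.get("mutation", "aa_class")),
        population_size=int(raw.get("population_size", 100)),
        generations=int(raw.get("generations", 50)),
        peptide_length=int(raw.get("peptide_length", DEFAULT_PEPTIDE_LENGTH)),
        seed=int(raw.get("seed", 0)),
    )
    return config, raw


def load_sweep_registry(
    raw: dict[str, Any],
) -> tuple[list[SelectionSpec], list[CrossoverSpec], list[FitnessFunction],
           list[MutationSpec]]:
    """Operator registries from a sweep config; omitted lists default to the
    full set (7 selection, 6 crossover, 5 bundled scorers, 2 mutation)."""
    selections = [
        _selection_spec(c)
        for c in raw.get("selection", list(SELECTION_OPERATORS))
    ]
    crossovers = [
        _crossover_spec(c)
        for c in raw.get("crossover", list(CROSSOVER_OPERATORS))
    ]
    if "fitness" in raw:
        fitnesses = [resolve_fitness(c) for c in raw["fitness"]]
    else:
        fitnesses = bundled_scorers()
    mutations = [
        _mutation_spec(c) for c in raw.get("mutation", list(MUTATION_OPERATORS))
    ]
    return selections, crossovers, fitnesses, mutations


def trajectory_frame(
    trajectory: Sequence[GenerationStats], **meta: Any
) -> pd.DataFrame:
    """Trajectory as a tidy table; `meta` columns (run_id, operator names...)
    are prepended to every row."""
    rows = []
    for s in trajectory:
        rows.append({
            **meta,
            "generation": s.generation,
            "median": s.median,
            "min": s.minimum,
            "max": s.maximum,
            "best_peptide": s.best_peptide,
            "best_fitness": s.best_fitness,
        })
    return pd.DataFrame(rows)


def sweep_frame(result: SweepResult) -> pd.DataFrame:
    """One row per (successful run, generation); failed cells get a single
    row with the error message in the `error` column."""
    frames = []
    for c in result.cells:
        meta = dict(run_id=c.run_id, selection=c.selection, crossover=c.crossover,
                    fitness=c.fitness, mutation=c.mutation)
        if c.ok:
            frames.append(trajectory_frame(c.trajectory, **meta))
        else:
            frames.append(pd.DataFrame([{**meta, "error": c.error}]))
    return pd.concat(frames, ignore_index=True)


def write_manifest(
    directory: str | Path,
    raw_config: dict[str, Any],
    seed: int,
    outputs: dict[str, str],
) -> Path:
    from . import __version__

    path = Path(directory) / "manifest.json"
    manifest = {
        "tool": "pepga",
        "version": __version__,
        "seed": seed,
        "config": raw_config,
        "outputs": outputs,
        "written_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
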