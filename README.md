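# pepga

Genetic-algorithm optimisation of peptides for MHC class I binding.

Most epitope-prediction workflows ask "how well does this peptide bind a
given MHC allele?". `pepga` asks the inverse question: **which peptides does
a given scoring function consider optimal binders?** Exhaustive screening is
hopeless — there are 20⁹ ≈ 5×10¹¹ possible nonamers, and at 10 evaluations
per second scoring them all would take more than 1,600 years
(20⁹ / (10·60·60·24·365)). A genetic algorithm explores the same search
space heuristically in minutes, and the interesting scientific question
becomes which GA *operators* drive the population to convergence.

The package is aimed at immunoinformaticians and anyone studying GA operator
behaviour on string genomes. It provides:

* **genomes & lifecycle** — fixed-length peptides over the 20-letter amino
  acid alphabet; populations of distinct individuals, with duplicates purged
  and replaced by fresh random peptides every generation (diversity
  maintenance);
* **7 selection operators** — roulette wheel (raw-proportional or
  rank-rescaled), linear rank, binary tournament, q-tournament, best-percent
  truncation, stochastic universal sampling, and a fitness-blind random
  control;
* **6 crossover operators** — single-point, double-point, distance-bisector
  (deterministic middle cut), multi-point with random cut count,
  uniform, and shuffle crossover; all obey positionwise allele conservation;
* **2 mutation operators** at a 3% per-position rate — class-changing amino
  acid substitution (unpolar/polar/basic/acidic) and codon-level nucleobase
  mutation with stop-codon avoidance;
* **pluggable fitness functions** with an explicit maximise/minimise
  orientation (IC50-style predictors are minimised), including additive
  position-scoring matrices, a Hamming-peak toy landscape with a known
  optimum, and an adapter that shells out to any external predictor;
* **a benchmark sweep** over every operator combination (the default
  registry is 7 × 6 × 5 × 2 = 420 independent runs of 50 generations × 100
  individuals = 2,100,000 peptide evaluations), plus downstream analyses:
  median-fitness convergence trajectories, consensus sequences, position
  frequency matrices / logo data, Van der Waals volumes, and Levenshtein
  comparison against reference peptide sets.

## The core loop

For a population P of n distinct peptides and a fitness function f with
orientation o:

```
generation 1:   P ← n random peptides, purge duplicates, evaluate f
generation g+1: parents  ← select(P, o)           (n parents, one of 7 schemes)
                children ← crossover(pairs)        (one of 6 operators)
                children ← mutate(children)        (3% per position, 1 of 2 models)
                P        ← purge(children)         (duplicates → fresh random)
                evaluate f on P, record median/min/max/best
```

The run always lasts a fixed number of generations (default 50) so that
operator combinations remain comparable.

## Worked example

```python
from pepga import (GAConfig, SelectionSpec, CrossoverSpec, MutationSpec,
                   bundled_scorers, run_ga)

scorer = next(f for f in bundled_scorers() if f.name == "pssm_a")
config = GAConfig(
    fitness=scorer,
    selection=SelectionSpec("binary_tournament"),
    crossover=CrossoverSpec("single_point"),
    mutation=MutationSpec("aa_class", rate=0.03),
    population_size=100, generations=50, seed=1,
)
trajectory, final = run_ga(config)
for s in trajectory[::10] + [trajectory[-1]]:
    print(f"generation {s.generation:>2}: median={s.median:5.1f} "
          f"best={s.best_peptide} ({s.best_fitness:g})")
```

prints

```
generation  1: median= 18.0 best=GGHSSGMCV (27)
generation 11: median= 32.0 best=ASHSWMMAI (35)
generation 21: median= 36.0 best=LYHSPKVAD (36)
generation 31: median= 36.0 best=LSVSYKMAD (36)
generation 41: median= 36.0 best=MSESPLNDD (36)
generation 50: median= 36.0 best=ASESYMNAC (36)
```

Generation 1 is the random starting population (median score 18 under this
scorer); tournament selection then drives the population median to the
scorer's plateau (36) within ~20 generations. The best peptide of the final
generation is the run's proposed high-affinity binder; because duplicates
are purged every generation, the final population is 100 *distinct*
near-optimal nonamers, not 100 copies of one winner.

Volumes of experimentally validated consensus nonamers:

```python
from pepga import vdw_volume
vdw_volume("YLAEGLASL")   # 877.0  (Å^3)
vdw_volume("YMMEWMWYV")   # 1194.0
vdw_volume("WWWWWWWWW")   # 1467.0 — the theoretical nonamer maximum
```

The `examples/` directory contains short narrative scripts for each
capability (single run, operator sweep, consensus/volume analysis,
reference comparison), and the `pepga` command-line tool exposes the same
operations as `pepga run | sweep | analyze | volume | compare`:

```bash
pepga run -c config.yaml -o out/      # trajectory TSV + final FASTA + manifest
pepga sweep -o grid_out/              # the full 420-run benchmark grid
pepga analyze peptides.fasta -o out/  # consensus, PFM, volumes
```

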