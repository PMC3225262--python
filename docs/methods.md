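# Methods

## Model and procedure

`pepga` implements a generational genetic algorithm over fixed-length
peptide strings. The genome is a string of L residues (default L = 9, the
MHC class I epitope length) over the 20 proteinogenic amino acids in fixed
alphabetical order `ACDEFGHIKLMNPQRSTVWY`; the fixed ordering makes every
"random residue" draw reproducible. A population holds n individuals
(default n = 100) and is kept free of duplicate peptides: after every
generation, later copies of an already-present peptide are replaced by
fresh random peptides, which counteracts genetic drift and keeps the
population from collapsing onto a single dominant sequence. Replacement
peptides are redrawn until they collide with nothing currently in the
population; the loop is capped (1,000 redraws per slot) and the operation
refuses populations larger than the sequence space.

Generation numbering: generation 1 is the evaluated random initial
population; each later generation is produced by selection → pairwise
crossover → mutation → purge → evaluation. Every individual entering a
generation's statistics is evaluated within that generation, so one run of
G generations costs exactly G·n fitness evaluations — the accounting that
makes the default benchmark sweep 420 × 50 × 100 = 2,100,000 evaluations.
Runs always last the configured number of generations (default 50, no early
stopping) so that different operator combinations remain comparable.
Parents are paired consecutively (1,2), (3,4), …; for odd n one extra
parent is selected and the final pair's second child is dropped. Offspring
fully replace the parents; elitist pressure exists only through the
best-percent selection scheme. Purging could in principle run before or
after mutation; we purge after mutation, immediately before evaluation, so
that the distinctness invariant holds for exactly the individuals being
scored.

## Fitness functions and orientation

A fitness function is a deterministic map peptide → ℝ plus an orientation.
Orientation lives in the fitness function, not the engine: predictors that
report binding strength directly are maximised, IC50-style predictors
(lower = stronger binding) are minimised, and every selection operator
consumes only *oriented* values (larger always better) or nonnegative
weights derived from them.

Weight transform for the wheel-based operators (roulette, SUS):

* `raw` mode — maximisation uses the raw scores (shifted up by the minimum
  plus ε = 10⁻⁹ · range only if negatives occur); minimisation reflects
  each score s to (max + min) − s. The reflection preserves the raw spread
  deliberately: on an IC50-like scale spanning [0, ~50,000], strong binders
  (< 500 nM) and mediocre peptides end up with nearly equal wheel areas, so
  plain roulette exerts almost no selection pressure — a failure mode the
  benchmark is designed to exhibit.
* `rescaled` mode — each score is replaced by its average (tie-sharing)
  rank on the oriented scale. Rank weights are scale-free, restoring full
  contrast regardless of how scores cluster; this is the bundled
  "transformation of the score distribution" remedy. A min–max rescaling
  was considered and rejected: it leaves scores clustered near the optimum
  as indistinguishable as the raw wheel does.

Bundled scorers: five fixed additive position-scoring matrices (L × 20
TSV fixtures) form the default sweep registry — `ic50_surrogate`
(orientation = minimise, per-cell weights uniform on [0, 5555] so peptide
scores span the IC50-like 0–50,000 range) and four maximised matrices on
assorted scales, one (`pssm_c`) with negative weights to exercise the
nonnegativity shift. They are arbitrary-but-fixed stand-ins generated once
from seed 20110617, chosen to reproduce the *structure* of a five-predictor
benchmark (orientations, scales, 7×6×5×2 arithmetic), not the behaviour of
any published predictor. Real predictors plug in through the external
command adapter (one peptide per line in, one score per line out) or as
user-supplied matrix files.

The Hamming-peak landscape (score = L − Hamming distance to a target)
provides a brute-force-verifiable testbed: its unique global optimum is the
target itself, so convergence claims can be checked against ground truth.

## Selection operators

All seven schemes share a signature (population, orientation, k, rng,
spec) → k parents with repetition, and all tie-breaks are stable in input
order, so population + seed + spec determine the parent list exactly.

* **roulette** — P(i) = wᵢ/Σw, independent draws, weight modes as above.
* **linear_rank** — ranks 1 (best) … N; P(rank i) =
  (1/N)(s − 2(s−1)(i−1)/(N−1)) with pressure s ∈ [1, 2], default 1.5
  (s = 1 uniform, s = 2 steepest).
* **binary_tournament** — two uniform picks with replacement; the strictly
  fitter wins with no further stochasticity; exact ties by fair coin.
* **random** — uniform, fitness-blind; the negative control.
* **best_percent** — the top ⌈N·percent/100⌉ individuals (default 10%)
  cycled in fitness order until k slots are filled; fully deterministic.
* **q_tournament** — every individual plays q tournaments (default q = 3),
  each against an opponent drawn uniformly from the *other* N−1 individuals
  (with replacement across tournaments); strict win = 1, fitness tie = 0.5;
  ranked by victories, ties by oriented fitness then input order. Excluding
  self-opponents is what guarantees the dominance property that the
  population's best can never lose a tournament; sampling opponents without
  replacement within one individual's q tournaments would be a further
  variant, not implemented.
* **sus** — stochastic universal sampling: one spin, k equally spaced
  pointers, single uniform offset in [0, Σw/k); each individual receives
  ⌊k·pᵢ⌋ or ⌈k·pᵢ⌉ copies (low-variance proportional selection).

Defaults for the unparameterised-in-the-field operators (percent = 10,
q = 3, s = 1.5, uniform-crossover threshold = 0.5) are conventional values;
all are configurable.

## Crossover operators

Cut convention: a cut at c (1-based, c ∈ {1, …, L−1}) separates positions
1..c from c+1..L, so no cut yields an empty segment. All six operators obey
positionwise allele conservation — {child1[i], child2[i]} = {p1[i], p2[i]}
as multisets — so crossover can rearrange but never invent residues.

single_point (uniform cut), double_point (two distinct cuts, middle
exchanged), distance_bisector (deterministic cut after ⌈L/2⌉ — position 5
for nonamers; for odd L the longer segment is the prefix), multi_point
(r ∼ uniform{1, …, L−1} distinct cuts, segments exchanged alternately
starting with the second; r = 1 reduces exactly to single_point — we cap r
at L−1 because an L-th cut after the last position would be a no-op under
the no-empty-segment convention), uniform (per-position independent U(0,1)
draw; draw > threshold swaps the position; threshold default 0.5), and
shuffle (one shared random permutation applied to both parents, strict
two-point crossover in shuffled space, inverse permutation applied to both
children — sharing the permutation is required for allele conservation).

## Mutation operators

Both operators act independently per position with probability `rate`
(default 0.03).

* **aa_class** — the residue is replaced by one drawn uniformly from the
  union of the three chemical classes it does not belong to. Partition
  (shipped as an editable TSV, standard textbook assignment): unpolar
  {A,V,L,I,P,F,M,W,G}, polar {S,T,C,Y,N,Q}, basic {K,R,H}, acidic {D,E}.
  A class mutation always changes the residue.
* **nucleobase** — the mutation happens at the DNA level: a codon for the
  residue is drawn uniformly among its synonymous codons (standard genetic
  code), one of its three bases is substituted by a uniformly drawn
  different base, and stop codons are avoided by redrawing the base
  substitution while keeping the chosen codon (minimal deviation from the
  drawn codon). The mutated codon's translation becomes the new residue;
  silent mutations are allowed, so the residue may survive. At most one
  base changes per selected position per generation. Drawing a random
  synonymous codon (rather than fixing a canonical codon per residue) is a
  choice; it is the natural uninformative prior over codon usage and is
  confined to one function if a canonical-codon variant is ever needed.

## Benchmark sweep and statistics

`sweep()` runs one independent GA per cell of the Cartesian product of the
operator registries (default 7 × 6 × 5 × 2 = 420 cells). Per-cell seeds are
derived from the base seed and the cell index through a seed sequence, so
the whole grid is reproducible bit-for-bit from one integer while cells
remain statistically independent. A failing cell records its diagnostic and
the sweep continues. Per generation the engine records median (even-size
convention: mean of the two central values), min, max, the best individual
(oriented comparison, first-in-population on ties) and the evaluation
count; the median trajectory is the convergence readout.

## Downstream analyses

Consensus = positionwise modal residue, ties broken alphabetically
(determinism). Position frequency matrices carry columnwise relative
frequencies; information content per column is log₂(20) − H (Shannon, bits)
following the standard logo convention, with the small-sample correction
(19/(2·ln 2·n)) available behind a flag but off by default. Van der Waals
volumes are additive per-residue sums over a bundled 20-residue table (ų);
the table jointly reproduces all six published checkpoint volumes (five
consensus nonamers and the 1467 ų poly-W maximum), which pins the values of
the twelve residues those peptides exercise; the remaining eight residues
carry the same standard compilation's values but are not pinned by the
checkpoints. Levenshtein distances are exact unit-cost edit distances
(computed with edlib's global alignment; verified in the tests against an
independent dynamic-programming implementation); `compare_to_reference`
reports each query's minimum distance to a reference set, the histogram of
minima and the exact-match count, with no banding or heuristics —
hundreds of queries × ~15k references is desk-scale.

## What the synthetic scorers do and do not show

The bundled additive matrices emulate the *interface* and *scale structure*
of sequence-based binding predictors: independent per-position
contributions, a minimised IC50-like scorer, heterogeneous score ranges.
They do not emulate real predictors' position couplings, training-set
biases, or anchor-residue preferences, so passing tests demonstrate the
correctness and comparative behaviour of the GA machinery (selection
pressure, convergence, diversity maintenance) — not that any particular
peptide is a real binder. Additive landscapes are also easier to optimise
than real predictor landscapes; convergence speeds measured here are upper
bounds in that sense. Conclusions about real MHC binding require plugging
in an actual predictor via the adapter.

## Test and verification scales

Statistical operator tests use seeded generators and sample sizes chosen so
the chi-square/binomial checks have comfortable power at significance
0.001 (10⁴–10⁵ draws). Convergence properties are checked on the
Hamming-peak landscape at the standard run configuration (100 individuals,
50 generations) over 20–40 seeds; the full 420-cell sweep is exercised once
at full scale (50 × 100), which completes in well under a minute per
hundred runs with the bundled scorers.

## Known limitations

Single fixed genome length per run; no post-translationally modified or
non-standard residues; no elitism beyond best-percent truncation; no
Boltzmann/sigma scaling; no order-based crossovers (PMX, cycle); no
insertion/deletion mutations or transition/transversion bias; no
early-stopping criterion; purging checks distinctness only within the
current generation, so a peptide eliminated earlier may reappear later. The
external-scorer adapter trusts the wrapped command to be deterministic; a
stochastic predictor would silently violate the fitness contract.
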