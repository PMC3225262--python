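"""Are the optimised peptides novel, or copies of known binders?

Optimises a small population against the toy Hamming-peak landscape, then
measures the minimum Levenshtein distance from each run's best peptide to a
mock reference set (standing in for a download of experimentally measured
binding affinities). Distance 0 = the optimiser rediscovered a known binder.
"""

from pepga import (
    CrossoverSpec,
    GAConfig,
    MutationSpec,
    SelectionSpec,
    best_individuals,
    compare_to_reference,
    hamming_peak_fitness,
    run_ga,
)

reference = ["YLAEGLASL", "FLWEVTPTV", "ILKEPVHGV", "GILGFVFTL", "NLVPMVATV"]

best = []
for seed in range(8):
    config = GAConfig(
        fitness=hamming_peak_fitness("MLWTMVFTV"),
        selection=SelectionSpec("q_tournament", q=3),
        crossover=CrossoverSpec("uniform"),
        mutation=MutationSpec("nucleobase", rate=0.03),
        population_size=100,
        generations=30,
        seed=seed,
    )
    trajectory, _ = run_ga(config)
    best.extend(best_individuals(trajectory, 30))

result = compare_to_reference(best, reference)
print("min Levenshtein distance -> number of optimised peptides")
for distance, count in result.histogram.items():
    print(f"{distance:>2} -> {count}")
print(f"exact matches: {result.exact_matches} of {result.n_queries}")

# Small minimum distances mean the optimiser converged near sequences already
# in the reference set; large ones mean it proposes genuinely novel binders.
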