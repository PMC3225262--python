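"""Selection-operator distributions against their closed-form contracts."""

import numpy as np
import pytest
import scipy.stats as st

from pepga import SELECTION_OPERATORS, SelectionSpec, ensure_rng, select_parents
from pepga.selection import (
    best_percent_select,
    binary_tournament_select,
    linear_rank_select,
    q_tournament_select,
    random_select,
    roulette_select,
    sus_select,
)

from conftest import make_population


def _counts(parents, pop):
    ids = {id(ind): i for i, ind in enumerate(pop.individuals)}
    out = np.zeros(len(pop.individuals), dtype=int)
    for p in parents:
        out[ids[id(p)]] += 1
    return out


class TestRoulette:
    def test_uniform_weights_select_uniformly(self):
        pop = make_population([2.0] * 5)
        rng = ensure_rng(0)
        counts = _counts(
            roulette_select(pop, "maximize", 10_000, rng, SelectionSpec("roulette")),
            pop,
        )
        assert st.chisquare(counts).pvalue > 0.001

    def test_three_to_one_weight_ratio(self):
        pop = make_population([3.0, 1.0])
        rng = ensure_rng(1)
        counts = _counts(
            roulette_select(pop, "maximize", 10_000, rng, SelectionSpec("roulette")),
            pop,
        )
        test = st.binomtest(int(counts[0]), 10_000, 0.75)
        assert test.pvalue > 0.001

    def test_minimisation_prefers_smaller_scores(self):
        pop = make_population([100.0, 300.0])
        rng = ensure_rng(2)
        counts = _counts(
            roulette_select(pop, "minimize", 10_000, rng, SelectionSpec("roulette")),
            pop,
        )
        assert st.binomtest(int(counts[0]), 10_000, 0.75).pvalue > 0.001

    def test_k_zero_rejected(self):
        pop = make_population([1.0, 2.0])
        with pytest.raises(ValueError):
            roulette_select(pop, "maximize", 0, ensure_rng(0), SelectionSpec("roulette"))


class TestLinearRank:
    def test_s_one_is_uniform(self):
        pop = make_population([5.0, 1.0, 3.0])
        rng = ensure_rng(3)
        spec = SelectionSpec("linear_rank", s=1.0)
        counts = _counts(linear_rank_select(pop, "maximize", 30_000, rng, spec), pop)
        assert st.chisquare(counts).pvalue > 0.001

    def test_n2_s2_best_always_wins(self):
        pop = make_population([1.0, 9.0])
        spec = SelectionSpec("linear_rank", s=2.0)
        parents = linear_rank_select(pop, "maximize", 200, ensure_rng(4), spec)
        assert all(p.fitness == 9.0 for p in parents)

    def test_n3_matches_formula(self):
        """N=3, s=1.5: P(rank i) = (1/3)(1.5 - (i-1)/2) = {0.5, 1/3, 1/6}."""
        pop = make_population([10.0, 20.0, 30.0])  # ranks: idx2 best, idx0 worst
        spec = SelectionSpec("linear_rank", s=1.5)
        counts = _counts(
            linear_rank_select(pop, "maximize", 30_000, ensure_rng(5), spec), pop
        )
        expected = 30_000 * np.array([1 / 6, 1 / 3, 1 / 2])
        assert st.chisquare(counts, expected).pvalue > 0.001

    def test_single_individual_population(self):
        pop = make_population([7.0])
        parents = linear_rank_select(
            pop, "maximize", 5, ensure_rng(0), SelectionSpec("linear_rank")
        )
        assert len(parents) == 5

    @pytest.mark.parametrize("s", [0.5, 2.5])
    def test_pressure_out_of_range_rejected(self, s):
        pop = make_population([1.0, 2.0])
        with pytest.raises(ValueError):
            linear_rank_select(
                pop, "maximize", 1, ensure_rng(0), SelectionSpec("linear_rank", s=s)
            )


class TestBinaryTournament:
    def test_strictly_fitter_always_wins(self):
        """No stochastic influence beyond the two picks: over many draws
        from a 2-individual population the weaker is only ever returned when
        drawn twice (probability 1/4)."""
        pop = make_population([5.0, 2.0])
        counts = _counts(
            binary_tournament_select(
                pop, "maximize", 40_000, ensure_rng(6), SelectionSpec("binary_tournament")
            ),
            pop,
        )
        assert st.binomtest(int(counts[1]), 40_000, 0.25).pvalue > 0.001

    def test_identical_fitnesses_select_uniformly(self):
        pop = make_population([4.0] * 6)
        counts = _counts(
            binary_tournament_select(
                pop, "maximize", 12_000, ensure_rng(7), SelectionSpec("binary_tournament")
            ),
            pop,
        )
        assert st.chisquare(counts).pvalue > 0.001

    def test_rank_probabilities_match_closed_form(self):
        """P(rank i wins a draw) = (2(N-i)+1)/N^2 under sampling with
        replacement, for N distinct fitnesses."""
        n = 10
        pop = make_population(list(range(n, 0, -1)))  # idx0 best ... idx9 worst
        counts = _counts(
            binary_tournament_select(
                pop, "maximize", 100_000, ensure_rng(8), SelectionSpec("binary_tournament")
            ),
            pop,
        )
        ranks = np.arange(1, n + 1)
        expected = 100_000 * (2 * (n - ranks) + 1) / n**2
        assert st.chisquare(counts, expected).pvalue > 0.001


class TestRandomSelect:
    def test_uniform(self):
        pop = make_population([1.0, 100.0, 3.0])
        counts = _counts(
            random_select(pop, "maximize", 12_000, ensure_rng(9), SelectionSpec("random")),
            pop,
        )
        assert st.chisquare(counts).pvalue > 0.001

    def test_fitness_invariance(self):
        """Permuting fitness values changes nothing: the same seed yields the
        same index sequence."""
        pop1 = make_population([1.0, 2.0, 3.0])
        pop2 = make_population([3.0, 1.0, 2.0])
        c1 = _counts(random_select(pop1, "maximize", 500, ensure_rng(10),
                                   SelectionSpec("random")), pop1)
        c2 = _counts(random_select(pop2, "maximize", 500, ensure_rng(10),
                                   SelectionSpec("random")), pop2)
        assert list(c1) == list(c2)

    def test_deterministic_given_seed(self):
        pop = make_population([1.0, 2.0, 3.0])
        a = random_select(pop, "maximize", 3, ensure_rng(11), SelectionSpec("random"))
        b = random_select(pop, "maximize", 3, ensure_rng(11), SelectionSpec("random"))
        assert [p.peptide for p in a] == [p.peptide for p in b]


class TestBestPercent:
    def test_twenty_percent_of_ten_cycles_two_elites(self):
        pop = make_population(list(range(10)))  # idx9 best, idx8 second
        spec = SelectionSpec("best_percent", percent=20)
        parents = best_percent_select(pop, "maximize", 10, ensure_rng(0), spec)
        fits = [p.fitness for p in parents]
        assert fits.count(9.0) == 5
        assert fits.count(8.0) == 5

    def test_hundred_percent_returns_population_in_fitness_order(self):
        pop = make_population([3.0, 1.0, 2.0])
        spec = SelectionSpec("best_percent", percent=100)
        parents = best_percent_select(pop, "maximize", 3, ensure_rng(0), spec)
        assert [p.fitness for p in parents] == [3.0, 2.0, 1.0]

    def test_ten_percent_of_ten_is_single_best(self):
        pop = make_population(list(range(10)))
        spec = SelectionSpec("best_percent", percent=10)
        parents = best_percent_select(pop, "maximize", 7, ensure_rng(0), spec)
        assert all(p.fitness == 9.0 for p in parents)

    def test_minimisation_orientation(self):
        pop = make_population([5.0, 1.0, 3.0])
        spec = SelectionSpec("best_percent", percent=33)  # ceil(0.99) = 1 elite
        parents = best_percent_select(pop, "minimize", 2, ensure_rng(0), spec)
        assert all(p.fitness == 1.0 for p in parents)

    @pytest.mark.parametrize("percent", [0, -1, 101])
    def test_percent_out_of_range_rejected(self, percent):
        pop = make_population([1.0])
        with pytest.raises(ValueError):
            best_percent_select(
                pop, "maximize", 1, ensure_rng(0),
                SelectionSpec("best_percent", percent=percent),
            )


class TestQTournament:
    def test_best_individual_cannot_lose(self):
        """The population's best accrues q victories in every seed, so it
        always heads the selection."""
        pop = make_population([1.0, 9.0, 4.0, 2.0])
        for seed in range(20):
            parents = q_tournament_select(
                pop, "maximize", 1, ensure_rng(seed), SelectionSpec("q_tournament", q=3)
            )
            assert parents[0].fitness == 9.0

    def test_replay_oracle(self):
        """Victory counts replayed with the same seed reproduce the selected
        order."""
        fits = [4.0, 1.0, 3.0, 2.0]
        pop = make_population(fits)
        q, seed, n = 3, 13, 4
        parents = q_tournament_select(
            pop, "maximize", 4, ensure_rng(seed), SelectionSpec("q_tournament", q=q)
        )
        rng = ensure_rng(seed)
        opponents = rng.integers(0, n - 1, size=(n, q))
        opponents += opponents >= np.arange(n)[:, None]
        ori = np.array(fits)
        victories = (ori[:, None] > ori[opponents]).sum(axis=1) + 0.5 * (
            ori[:, None] == ori[opponents]
        ).sum(axis=1)
        order = sorted(range(n), key=lambda i: (-victories[i], -ori[i], i))
        assert [p.fitness for p in parents] == [fits[i] for i in order]

    def test_expected_victories_increase_with_fitness(self):
        """Monte-Carlo over many seeds: mean victory counts are strictly
        monotone in fitness rank."""
        fits = [1.0, 2.0, 3.0, 4.0, 5.0]
        pop = make_population(fits)
        totals = np.zeros(5)
        for seed in range(2000):
            parents = q_tournament_select(
                pop, "maximize", 5, ensure_rng(seed), SelectionSpec("q_tournament", q=4)
            )
            # rank position in the returned (victory-ordered) list
            for pos, p in enumerate(parents):
                totals[int(p.fitness) - 1] += 5 - pos
        assert all(np.diff(totals) > 0)

    def test_q_out_of_range_rejected(self):
        pop = make_population([1.0, 2.0])
        with pytest.raises(ValueError):
            q_tournament_select(
                pop, "maximize", 1, ensure_rng(0), SelectionSpec("q_tournament", q=0)
            )


class TestSUS:
    def test_exact_counts_for_integral_expectations(self):
        """Weights {0.5, 0.3, 0.2} with k=10: every offset yields exactly
        {5, 3, 2} copies."""
        pop = make_population([0.5, 0.3, 0.2])
        for seed in range(50):
            counts = _counts(
                sus_select(pop, "maximize", 10, ensure_rng(seed), SelectionSpec("sus")),
                pop,
            )
            assert list(counts) == [5, 3, 2]

    def test_uniform_weights_select_everyone_once(self):
        pop = make_population([2.0] * 8)
        counts = _counts(
            sus_select(pop, "maximize", 8, ensure_rng(0), SelectionSpec("sus")), pop
        )
        assert list(counts) == [1] * 8

    def test_copy_counts_within_floor_ceil_bounds(self):
        """SUS low-variance guarantee over 1,000 seeds."""
        weights = [5.0, 1.0, 2.5, 0.5, 1.0]
        pop = make_population(weights)
        p = np.array(weights) / sum(weights)
        k = 12
        for seed in range(1000):
            counts = _counts(
                sus_select(pop, "maximize", k, ensure_rng(seed), SelectionSpec("sus")),
                pop,
            )
            assert np.all(counts >= np.floor(k * p))
            assert np.all(counts <= np.ceil(k * p))


class TestSharedContracts:
    @pytest.mark.parametrize("operator", sorted(SELECTION_OPERATORS))
    def test_returns_k_members_of_population(self, operator):
        pop = make_population([1.0, 4.0, 2.0, 3.0])
        parents = select_parents(
            pop, "maximize", 7, ensure_rng(1), SelectionSpec(operator)
        )
        assert len(parents) == 7
        members = {id(ind) for ind in pop.individuals}
        assert all(id(p) in members for p in parents)

    @pytest.mark.parametrize("operator", sorted(SELECTION_OPERATORS))
    def test_deterministic_given_seed(self, operator):
        pop = make_population([1.0, 4.0, 2.0, 3.0])
        a = select_parents(pop, "maximize", 6, ensure_rng(2), SelectionSpec(operator))
        b = select_parents(pop, "maximize", 6, ensure_rng(2), SelectionSpec(operator))
        assert [p.peptide for p in a] == [p.peptide for p in b]

    @pytest.mark.parametrize(
        "operator", sorted(set(SELECTION_OPERATORS) - {"random"})
    )
    def test_better_fitness_never_hurts_selection(self, operator):
        """Monte-Carlo monotonicity: boosting one individual's fitness to the
        top never decreases its selection frequency."""
        base = [1.0, 2.0, 3.0, 4.0]
        boosted = [1.0, 6.0, 3.0, 4.0]
        spec = SelectionSpec(operator)
        n_base = n_boost = 0
        for seed in range(400):
            pop_b = make_population(base)
            pop_h = make_population(boosted)
            sel_b = select_parents(pop_b, "maximize", 4, ensure_rng(seed), spec)
            sel_h = select_parents(pop_h, "maximize", 4, ensure_rng(seed), spec)
            n_base += sum(1 for p in sel_b if p is pop_b.individuals[1])
            n_boost += sum(1 for p in sel_h if p is pop_h.individuals[1])
        assert n_boost >= n_base

    def test_unknown_operator_rejected_with_listing(self):
        pop = make_population([1.0])
        with pytest.raises(ValueError, match="binary_tournament"):
            select_parents(pop, "maximize", 1, ensure_rng(0), SelectionSpec("elitist"))

    def test_unevaluated_population_rejected(self):
        from pepga import Individual, Population

        pop = Population([Individual("AAAAAAAAA")], size=1)
        with pytest.raises(ValueError, match="evaluated"):
            select_parents(pop, "maximize", 1, ensure_rng(0), SelectionSpec("random"))
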