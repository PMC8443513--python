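import numpy as np
import pytest

import crossim as cs
from crossim.errors import ParameterError

from conftest import make_population


@pytest.fixture
def unlinked_two_marker_setup():
    """Two markers on different groups, homozygous contrasting parents, and
    a known model: the exact F2 distribution is enumerable."""
    gmap = cs.GeneticMap(
        group_lengths=[150.0, 150.0], locus_ids=("m1", "m2"),
        locus_group=[0, 1], pos_cM=[50.0, 50.0],
    )
    pop = make_population(gmap, [[1, 1], [-1, -1]])
    model = cs.PredictionModel(intercept=0.0, coef=[1.0, 0.5],
                               marker_ids=("m1", "m2"), lambda_=0.0)
    return gmap, pop, model


class TestScoreCross:
    def test_top_and_bottom_tail_means(self):
        pvs = np.array([1.0, 2.0, 3.0, 4.0])
        assert cs.score_cross(pvs, 2, "high")[0] == pytest.approx(3.5)
        assert cs.score_cross(pvs, 2, "low")[0] == pytest.approx(1.5)

    def test_constant_progeny(self):
        score, var = cs.score_cross(np.full(10, 2.5), 3, "high")
        assert score == 2.5 and var == 0.0

    def test_k_bounds(self):
        with pytest.raises(ParameterError):
            cs.score_cross(np.arange(4.0), 5, "high")
        with pytest.raises(ParameterError):
            cs.score_cross(np.arange(4.0), 0, "high")


class TestSimulateCrossProgeny:
    def test_progeny_count_five_f1_times_fifty_f2(self, rng,
                                                  unlinked_two_marker_setup):
        gmap, pop, model = unlinked_two_marker_setup
        pvs = cs.simulate_cross_progeny(
            pop.individual(0), pop.individual(1), gmap, model, 5, 50, rng
        )
        assert pvs.shape == (250,)

    def test_identical_homozygous_parents_breed_true(self, rng,
                                                     unlinked_two_marker_setup):
        gmap, pop, model = unlinked_two_marker_setup
        p = pop.individual(0)
        pvs = cs.simulate_cross_progeny(p, p, gmap, model, 5, 40, rng)
        parent_pv = cs.predict(model, p.codes().astype(float))
        assert np.all(pvs == parent_pv)
        assert cs.score_cross(pvs, 10, "high")[1] == 0.0

    def test_f2_codes_are_valid_genotypes(self, rng,
                                          unlinked_two_marker_setup):
        gmap, pop, model = unlinked_two_marker_setup
        pvs, codes = cs.simulate_cross_progeny(
            pop.individual(0), pop.individual(1), gmap, model, 5, 40, rng,
            return_codes=True,
        )
        assert codes.shape == (200, 2)
        assert set(np.unique(codes)) <= {-1, 0, 1}
        np.testing.assert_allclose(pvs, codes.astype(float) @ [1.0, 0.5])


class TestExactF2Oracle:
    def test_top_k_score_matches_independent_enumeration(self,
                                                         unlinked_two_marker_setup):
        """For two unlinked markers and contrasting homozygous parents the F2
        genotype distribution is exactly (1/4, 1/2, 1/4) per marker,
        independent across markers.  An oracle that samples codes directly
        from that distribution (never touching the meiosis engine) must give
        the same expected top-k score."""
        gmap, pop, model = unlinked_two_marker_setup
        k, n_prog, reps = 10, 200, 120
        rng_o = np.random.default_rng(101)
        oracle_scores = []
        for _ in range(reps):
            codes = rng_o.choice([-1, 0, 1], p=[0.25, 0.5, 0.25],
                                 size=(n_prog, 2)).astype(float)
            pvs = codes @ np.array([1.0, 0.5])
            oracle_scores.append(np.sort(pvs)[-k:].mean())
        rng_s = np.random.default_rng(202)
        sim_scores = []
        for _ in range(reps):
            pvs = cs.simulate_cross_progeny(
                pop.individual(0), pop.individual(1), gmap, model, 5, 40,
                rng_s,
            )
            sim_scores.append(cs.score_cross(pvs, k, "high")[0])
        se = np.sqrt(
            (np.var(oracle_scores, ddof=1) + np.var(sim_scores, ddof=1)) / reps
        )
        assert abs(np.mean(sim_scores) - np.mean(oracle_scores)) < 4 * se


class TestRankAllCrosses:
    def test_candidate_count_and_ordering(self, rng):
        gmap = cs.build_genome(5, 150.0, 10, rng)
        pop = cs.make_initial_population(gmap, 6, rng)
        model = cs.PredictionModel(
            intercept=0.0, coef=np.linspace(0.1, 1.0, 10),
            marker_ids=gmap.locus_ids, lambda_=0.0,
        )
        ranking = cs.rank_all_crosses(pop, model, n_f1=2, n_f2_per_f1=10,
                                      k=2, rng=rng)
        assert len(ranking) == 15  # C(6,2)
        scores = [c.score for c in ranking]
        assert scores == sorted(scores, reverse=True)
        assert [c.rank for c in ranking] == list(range(1, 16))
        for c in ranking:
            assert c.parent1 < c.parent2

    def test_low_direction_sorts_ascending(self, rng):
        gmap = cs.build_genome(3, 150.0, 6, rng)
        pop = cs.make_initial_population(gmap, 5, rng)
        model = cs.PredictionModel(intercept=0.0, coef=np.ones(6),
                                   marker_ids=gmap.locus_ids, lambda_=0.0)
        ranking = cs.rank_all_crosses(pop, model, n_f1=2, n_f2_per_f1=10,
                                      k=2, direction="low", rng=rng)
        scores = [c.score for c in ranking]
        assert scores == sorted(scores)

    def test_homozygous_parents_make_ranking_f1_count_invariant(self):
        """RIL parents produce a unique F1, so splitting the same total
        progeny over more F1 changes nothing but Monte-Carlo noise."""
        rng = np.random.default_rng(33)
        gmap = cs.build_genome(4, 150.0, 8, rng)
        pop = cs.make_initial_population(gmap, 8, rng)
        # force full homozygosity (true RILs)
        haps = pop.haplotypes.copy()
        haps[:, 1] = haps[:, 0]
        pop = cs.Population(haplotypes=haps, gmap=gmap, ids=pop.ids)
        model = cs.PredictionModel(intercept=0.0, coef=rng.normal(size=8),
                                   marker_ids=gmap.locus_ids, lambda_=0.0)

        def mean_scores(n_f1, n_f2, seed):
            out = np.zeros(28)  # C(8,2) pairs in sorted order
            reps = 30
            for r in range(reps):
                rk = cs.rank_all_crosses(
                    pop, model, n_f1=n_f1, n_f2_per_f1=n_f2, k=10,
                    rng=np.random.default_rng(seed + r),
                )
                pair_scores = {(c.parent1, c.parent2): c.score for c in rk}
                out += np.array([pair_scores[p] for p in sorted(pair_scores)])
            return out / reps

        a = mean_scores(1, 200, 1000)
        b = mean_scores(5, 40, 2000)
        assert np.max(np.abs(a - b)) < 0.25

    def test_same_seed_same_ranking(self, rng):
        gmap = cs.build_genome(3, 150.0, 6, rng)
        pop = cs.make_initial_population(gmap, 6, rng)
        model = cs.PredictionModel(intercept=0.0, coef=np.ones(6),
                                   marker_ids=gmap.locus_ids, lambda_=0.0)
        r1 = cs.rank_all_crosses(pop, model, rng=np.random.default_rng(9))
        r2 = cs.rank_all_crosses(pop, model, rng=np.random.default_rng(9))
        assert [(c.parent1, c.parent2, c.score) for c in r1] == [
            (c.parent1, c.parent2, c.score) for c in r2
        ]


class TestPlanConstruction:
    def _pop_and_model(self, n, rng):
        gmap = cs.build_genome(2, 150.0, 4, rng)
        pop = cs.make_initial_population(gmap, n, rng)
        model = cs.PredictionModel(intercept=0.0, coef=np.ones(4),
                                   marker_ids=gmap.locus_ids, lambda_=0.0)
        return pop, model

    def test_p1_is_single_cross_of_top_two(self, rng):
        pop, model = self._pop_and_model(12, rng)
        plan = cs.select_strategy_P(pop, model, 1)
        assert len(plan.crosses) == 1 and plan.total_f1 == 10
        pv = cs.predict(model, pop.codes().astype(float))
        order = np.lexsort((np.arange(len(pop)), -pv))
        assert {plan.crosses[0].parent1, plan.crosses[0].parent2} == {
            int(order[0]), int(order[1])
        }

    def test_p10_round_robin_chain(self, rng):
        pop, model = self._pop_and_model(15, rng)
        plan = cs.select_strategy_P(pop, model, 10)
        assert len(plan.crosses) == 10 and plan.total_f1 == 10
        pv = cs.predict(model, pop.codes().astype(float))
        top = np.lexsort((np.arange(len(pop)), -pv))[:10]
        expected = {frozenset((int(top[i]), int(top[(i + 1) % 10])))
                    for i in range(10)}
        got = {frozenset((c.parent1, c.parent2)) for c in plan.crosses}
        assert got == expected

    def test_p5_allots_two_f1_per_cross(self, rng):
        pop, model = self._pop_and_model(10, rng)
        plan = cs.select_strategy_P(pop, model, 5)
        assert len(plan.crosses) == 5
        assert all(c.n_f1 == 2 for c in plan.crosses)

    def test_round_robin_of_three_wraps(self):
        assert cs.round_robin_pairs([4, 7, 9]) == [(4, 7), (7, 9), (9, 4)]

    def test_s1_plan_shape(self, rng):
        pop, model = self._pop_and_model(6, rng)
        plan = cs.select_strategy_S(pop, model, 1, n_f1=2, n_f2_per_f1=10,
                                    k=2, rng=rng)
        assert plan.strategy == "S1"
        assert len(plan.crosses) == 1 and plan.crosses[0].n_f1 == 10
        assert plan.crosses[0].candidate.rank == 1

    def test_s5_on_two_plants_is_an_error(self, rng):
        pop, model = self._pop_and_model(2, rng)
        with pytest.raises(ParameterError):
            cs.select_strategy_S(pop, model, 5, rng=rng)

    def test_insufficient_population_for_p10(self, rng):
        pop, model = self._pop_and_model(8, rng)
        with pytest.raises(ParameterError):
            cs.select_strategy_P(pop, model, 10)


class TestNextGeneration:
    def test_budget_split_equally_over_f1(self, rng):
        gmap = cs.build_genome(2, 150.0, 4, rng)
        pop = cs.make_initial_population(gmap, 12, rng)
        model = cs.PredictionModel(intercept=0.0, coef=np.ones(4),
                                   marker_ids=gmap.locus_ids, lambda_=0.0)
        plan = cs.select_strategy_P(pop, model, 10)
        nxt = cs.next_generation(plan, pop, n_f2_total=200, rng=rng)
        assert len(nxt) == 200

    def test_s1_progeny_descend_from_one_pair(self, rng):
        gmap = cs.build_genome(2, 150.0, 4, rng)
        pop = cs.make_initial_population(gmap, 6, rng)
        model = cs.PredictionModel(intercept=0.0, coef=np.ones(4),
                                   marker_ids=gmap.locus_ids, lambda_=0.0)
        plan = cs.select_strategy_S(pop, model, 1, n_f1=2, n_f2_per_f1=10,
                                    k=2, rng=rng)
        nxt = cs.next_generation(plan, pop, n_f2_total=40, rng=rng)
        a, b = plan.crosses[0].parent1, plan.crosses[0].parent2
        assert len(nxt) == 40
        assert all(f"_{a}x{b}_" in iid for iid in nxt.ids)

    def test_indivisible_budget_rejected(self, rng):
        gmap = cs.build_genome(2, 150.0, 4, rng)
        pop = cs.make_initial_population(gmap, 12, rng)
        model = cs.PredictionModel(intercept=0.0, coef=np.ones(4),
                                   marker_ids=gmap.locus_ids, lambda_=0.0)
        plan = cs.select_strategy_P(pop, model, 10)
        with pytest.raises(ParameterError):
            cs.next_generation(plan, pop, n_f2_total=205, rng=rng)


def test_enumerate_cross_pairs_counts():
    i1, i2 = cs.enumerate_cross_pairs(3)
    assert i1.size == 3
    assert np.all(i1 < i2)
    with pytest.raises(ParameterError):
        cs.enumerate_cross_pairs(1)
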