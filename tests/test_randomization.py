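"""Test statistics and randomization tests against exact oracles."""

import numpy as np
import pytest

from popcompare import (
    DEATH,
    composition_vector,
    concat_tables,
    planned_comparison,
    randomization_test,
    sss_distance_test,
    stat_scalar_global,
    stat_scalar_pairwise,
    stat_vector_global,
    stat_vector_pairwise,
)
from popcompare.engine import compile_tables, evaluate_parameter
from popcompare.randomization import UnreliableResultWarning
from popcompare.resampling import ResamplingPlan
from popcompare import VitalRateSpec, implied_matrices, simulate_table, stable_stage_structure
from popcompare.histories import histories_from_matrix
from popcompare.demography import ProjectionModel

from conftest import exhaustive_permutation_distribution, make_table


class TestStatistics:
    def test_scalar_pairwise(self):
        assert stat_scalar_pairwise(1.2, 1.0) == pytest.approx(0.2)
        assert stat_scalar_pairwise(3.0, 3.0) == 0.0
        assert stat_scalar_pairwise(1.0, 2.5) == stat_scalar_pairwise(2.5, 1.0)

    def test_scalar_global(self):
        assert stat_scalar_global([1, 2, 3]) == pytest.approx(2.0)
        assert stat_scalar_global([4.2] * 5) == 0.0

    def test_vector_pairwise(self):
        assert stat_vector_pairwise([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == 0.0
        assert stat_vector_pairwise([1, 0], [0, 1]) == 1.0
        assert stat_vector_pairwise([0.5, 0.5], [0.8, 0.2]) == pytest.approx(0.3)

    def test_vector_global(self):
        P = np.array([[1, 0], [0, 1], [0.5, 0.5]])
        assert stat_vector_global(P) == pytest.approx(0.5)
        assert stat_vector_global(np.tile([0.3, 0.7], (4, 1))) == 0.0

    def test_two_population_identities(self):
        # dg = dw^2/2 and Dg = Dw when exactly two populations are compared
        rng = np.random.default_rng(42)
        for _ in range(1000):
            x1, x2 = rng.normal(size=2)
            assert stat_scalar_global([x1, x2]) == pytest.approx(
                stat_scalar_pairwise(x1, x2) ** 2 / 2, rel=1e-12, abs=1e-12
            )
            m = rng.integers(2, 6)
            p = rng.dirichlet(np.ones(m), size=2)
            assert stat_vector_global(p) == pytest.approx(
                stat_vector_pairwise(p[0], p[1]), rel=1e-12, abs=1e-12
            )

    def test_global_vector_statistic_bounds(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            n, m = rng.integers(2, 6), rng.integers(2, 8)
            P = rng.dirichlet(np.ones(m), size=n)
            assert 0.0 <= stat_vector_global(P) <= 1.0


class TestRandomizationTest:
    def test_two_vs_two_exhaustive_null(self):
        # Two groups holding two copies of one history each; the exact null of
        # the history-composition statistic over the 6 allocations is
        # {1, 1, 0, 0, 0, 0}/6 and nothing exceeds the observed Dw = 1.
        a = make_table([0, 0], [1, 1], np.zeros((2, 2)), population_id="A")
        b = make_table([0, 0], [DEATH, DEATH], np.zeros((2, 2)), population_id="B")

        pooled = concat_tables([a, b], "pool")

        def stat(groups):
            parts = [pooled.subset(g) for g in groups]
            _, P = composition_vector(parts)
            return stat_vector_pairwise(P[0], P[1])

        exact = exhaustive_permutation_distribution([a, b], stat)
        np.testing.assert_allclose(sorted(exact), [0, 0, 0, 0, 1, 1])
        res = randomization_test([a, b], "histories", ResamplingPlan(6000, seed=0), mode="pairwise")
        assert res.observed == pytest.approx(1.0)
        assert res.p_value == 0.0
        # Monte-Carlo null matches the exact distribution
        assert np.mean(res.replicates == 1.0) == pytest.approx(2 / 6, abs=0.02)

    @pytest.mark.parametrize("parameter", ["lambda", "histories"])
    def test_monte_carlo_matches_exhaustive_p(self, parameter):
        # pooled size 10: Monte-Carlo p within 3 binomial SE of the exact p
        rng = np.random.default_rng(1)
        a = make_table(rng.integers(0, 2, 5), rng.integers(-1, 2, 5),
                       rng.poisson(1.0, (5, 2)), population_id="A")
        b = make_table(rng.integers(0, 2, 5), np.abs(rng.integers(-1, 2, 5)),
                       rng.poisson(2.0, (5, 2)), population_id="B")
        pooled = concat_tables([a, b], "pool")
        basis, _ = compile_tables([a, b])

        def stat(groups):
            cs = np.vstack([basis.counts_of(pooled.subset(g)) for g in groups])
            vals = evaluate_parameter(basis, cs, parameter)
            if parameter == "lambda":
                return stat_scalar_pairwise(vals[0], vals[1])
            return stat_vector_pairwise(vals[0], vals[1])

        exact = exhaustive_permutation_distribution([a, b], stat)
        obs = stat([np.arange(5), np.arange(5, 10)])
        p_exact = np.mean(exact > obs + 1e-12)
        n_reps = 10_000
        res = randomization_test([a, b], parameter, ResamplingPlan(n_reps, seed=2), mode="pairwise")
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / n_reps)
        assert res.p_value == pytest.approx(p_exact, abs=max(3 * se, 1e-3))

    def test_global_statistic_invariant_to_table_order(self, two_tables):
        a, b = two_tables
        r1 = randomization_test([a, b], "lambda", ResamplingPlan(999, seed=3))
        r2 = randomization_test([b, a], "lambda", ResamplingPlan(999, seed=3))
        assert r1.observed == pytest.approx(r2.observed, rel=1e-12)

    def test_undefined_T_replicates_are_skipped_and_flagged(self):
        # One reproducer per population: allocations sending both reproducers
        # to the same group make R0 = 0 (T undefined) in the other -> 1/3 of
        # replicates skipped, beyond the 10% reliability threshold.
        r = make_table([0, 0], [DEATH, DEATH], [[3, 0], [0, 0]], stage_names=("s1",),
                       recruits=None) if False else None
        a = make_table([0, 0], [DEATH, DEATH], np.array([[3], [0]]), stage_names=("s1",), population_id="A")
        b = make_table([0, 0], [DEATH, DEATH], np.array([[3], [0]]), stage_names=("s1",), population_id="B")
        with pytest.warns(UnreliableResultWarning):
            res = randomization_test([a, b], "T", ResamplingPlan(3000, seed=4), mode="pairwise")
        assert res.unreliable
        assert res.n_skipped == pytest.approx(res.n_reps / 3, rel=0.15)

    def test_observed_undefined_T_is_an_error(self):
        a = make_table([0], [DEATH], np.array([[0]]), stage_names=("s1",), population_id="A")
        b = make_table([0], [DEATH], np.array([[2]]), stage_names=("s1",), population_id="B")
        with pytest.raises(ValueError, match="undefined"):
            randomization_test([a, b], "T", ResamplingPlan(999, seed=5), mode="pairwise")

    def test_incompatible_populations_rejected(self, two_tables):
        other = make_table([0], [0], np.zeros((1, 3)), stage_names=("x", "y", "z"))
        with pytest.raises(ValueError, match="stages"):
            randomization_test([two_tables[0], other], "lambda", ResamplingPlan(999, seed=6))


class TestPlannedComparison:
    def test_pooled_sizes_and_contrast_validation(self, two_tables, base_spec):
        c = simulate_table(base_spec, 77, "C")
        tables = [*two_tables, c]
        res = planned_comparison(tables, [[[0, 1], [2]]], "histories", ResamplingPlan(499, seed=7))
        assert res[0].populations == ("A+B", "C")
        with pytest.raises(ValueError, match="disjoint"):
            planned_comparison(tables, [[[0, 1], [1]]], "lambda", ResamplingPlan(999, seed=8))

    def test_identical_groups_give_zero_statistic(self, two_tables):
        a = two_tables[0]
        b = a.subset(np.arange(a.n), population_id="B")
        res = planned_comparison([a, b], [[[0], [1]]], "histories", ResamplingPlan(499, seed=9))
        assert res[0].observed == 0.0

    def test_pooling_equals_concatenated_pairwise_test(self, two_tables, base_spec):
        c = simulate_table(base_spec, 78, "C")
        tables = [*two_tables, c]
        res = planned_comparison(tables, [[[0, 1], [2]]], "lambda", ResamplingPlan(999, seed=10))
        merged = concat_tables(tables[:2], "A+B")
        direct = randomization_test([merged, c], "lambda", ResamplingPlan(999, seed=10), mode="pairwise")
        assert res[0].observed == pytest.approx(direct.observed, rel=1e-12)
        assert res[0].p_value == pytest.approx(direct.p_value, abs=1e-12)

    def test_nonorthogonal_sets_are_flagged(self, two_tables, base_spec):
        c = simulate_table(base_spec, 79, "C")
        tables = [*two_tables, c]
        res = planned_comparison(
            tables, [[[0], [2]], [[1], [2]]], "histories", ResamplingPlan(499, seed=11)
        )
        assert all(r.nonorthogonal for r in res)


class TestSssDistanceTest:
    def test_population_exactly_at_sss(self):
        model = ProjectionModel(
            ("s1", "s2"),
            F=np.array([[0, 2.0], [0, 0]]),
            U=np.array([[0, 0], [0.5, 0]]),
            n_per_stage=np.array([20, 10]),  # = SSS (2/3, 1/3) of the cycle
        )
        table = histories_from_matrix(model)
        res = sss_distance_test(table, ResamplingPlan(999, seed=12))
        assert res.observed == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9

    def test_fixed_design_is_refused(self, base_spec):
        from dataclasses import replace

        spec = replace(base_spec, sampling="fixed_per_stage")
        table = simulate_table(spec, 13, "A")
        with pytest.raises(ValueError, match="meaningless"):
            sss_distance_test(table)

    def test_relabeling_invariance(self, base_spec):
        table = simulate_table(base_spec, 14, "A")
        swapped = make_table(
            1 - table.initial,
            np.where(table.fate == DEATH, DEATH, 1 - table.fate),
            table.recruits[:, ::-1],
            stage_names=("adult", "juvenile"),
            population_id="A",
        )
        r1 = sss_distance_test(table, ResamplingPlan(499, seed=15))
        r2 = sss_distance_test(swapped, ResamplingPlan(499, seed=15))
        assert r1.observed == pytest.approx(r2.observed, abs=1e-12)

    def test_p_value_roughly_uniform_under_self_sss(self, base_spec):
        # populations drawn at the SSS of their own vital rates: the distance
        # test should be well calibrated (p approximately uniform)
        from dataclasses import replace
        from scipy import stats

        F, U = implied_matrices(base_spec)
        sss = stable_stage_structure(F + U)
        spec = replace(base_spec, n_per_stage=np.rint(sss * 200).astype(int))
        rng = np.random.default_rng(16)
        pvals = []
        for i in range(200):
            table = simulate_table(spec, rng, f"sim{i}")
            res = sss_distance_test(table, ResamplingPlan(499, seed=1000 + i))
            pvals.append(res.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001
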