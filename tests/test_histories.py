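"""Life-history tables: raw-data conversion, matrix estimation, round trips."""

import numpy as np
import pandas as pd
import pytest

from popcompare import (
    DEATH,
    ProjectionModel,
    RawDataset,
    composition_vector,
    concat_tables,
    dominant_eigenvalue,
    histories_from_matrix,
    histories_from_raw,
    project_matrix,
)
from popcompare.histories import largest_remainder

from conftest import make_table


def _raw(records, **meta):
    defaults = dict(
        stage_names=("s1", "s2"),
        reproduction_type="identified",
        census="prebreeding",
        sampling="random",
    )
    defaults.update(meta)
    return RawDataset(data=pd.DataFrame(records), **defaults)


def _record(i, pop, s0, s1, rec=""):
    return {
        "individual_id": f"i{i}",
        "population_id": pop,
        "initial_stage": s0,
        "final_stage": s1,
        "recruits": rec,
    }


class TestHistoriesFromRaw:
    def test_four_records_two_patterns(self):
        raw = _raw(
            [
                _record(1, "A", "s1", "s2"),
                _record(2, "A", "s1", "s2"),
                _record(3, "A", "s1", "DEAD"),
                _record(4, "A", "s1", "DEAD"),
            ]
        )
        (table,) = histories_from_raw(raw)
        assert table.n == 4
        uniq, counts = table.distinct_histories()
        assert uniq.shape[0] == 2
        np.testing.assert_array_equal(sorted(counts), [2, 2])

    def test_anon1_totals_stored_at_population_level(self):
        raw = _raw(
            [_record(1, "A", "s2", "s2"), _record(2, "A", "s2", "DEAD")],
            reproduction_type="anon1",
            reproductive_stages=("s2",),
            recruit_totals={"A": {"s1": 20}},
        )
        (table,) = histories_from_raw(raw)
        assert not table.recruits.any()
        np.testing.assert_array_equal(table.recruit_totals, [20, 0])
        model = project_matrix(table)
        # 20 recruits credited to 2 reproductive stage-2 individuals
        assert model.F[0, 1] == pytest.approx(10.0)

    def test_anon1_rejects_per_individual_recruits(self):
        raw = _raw(
            [_record(1, "A", "s2", "s2", "s1:3")],
            reproduction_type="anon1",
            reproductive_stages=("s2",),
            recruit_totals={"A": {"s1": 3}},
        )
        with pytest.raises(ValueError, match="anon"):
            histories_from_raw(raw)

    def test_unknown_stage_label(self):
        raw = _raw([_record(1, "A", "s9", "s1")])
        with pytest.raises(ValueError, match="unknown stage"):
            histories_from_raw(raw)

    def test_empty_dataset(self):
        raw = _raw([])
        raw.data = pd.DataFrame(columns=["individual_id", "population_id", "initial_stage", "final_stage", "recruits"])
        with pytest.raises(ValueError):
            histories_from_raw(raw)


class TestProjectMatrix:
    def test_transition_frequency(self):
        table = make_table([0, 0, 0, 0], [1, 1, DEATH, DEATH], np.zeros((4, 2)))
        model = project_matrix(table)
        assert model.U[1, 0] == pytest.approx(0.5)
        assert model.U.sum() == pytest.approx(0.5)

    def test_fecundity_average(self):
        # 10 stage-2 individuals jointly produce 20 stage-1 recruits
        rec = np.zeros((10, 2), dtype=int)
        rec[:, 0] = 2
        table = make_table([1] * 10, [1] * 10, rec)
        model = project_matrix(table)
        assert model.F[0, 1] == pytest.approx(2.0)

    def test_everyone_dies(self):
        table = make_table([0, 1], [DEATH, DEATH], np.zeros((2, 2)))
        model = project_matrix(table)
        assert not model.U.any() and not model.F.any()
        assert dominant_eigenvalue(model.A) == 0.0

    def test_column_stochasticity_exact(self):
        rng = np.random.default_rng(5)
        n = 50
        table = make_table(
            rng.integers(0, 2, n),
            rng.integers(-1, 2, n),
            rng.poisson(0.5, size=(n, 2)),
        )
        model = project_matrix(table)
        death_freq = np.array(
            [
                np.mean(table.fate[table.initial == j] == DEATH) if (table.initial == j).any() else 0
                for j in range(2)
            ]
        )
        np.testing.assert_allclose(model.U.sum(axis=0) + death_freq, 1.0, atol=1e-12)


class TestHistoriesFromMatrix:
    def test_exact_multiples(self):
        model = ProjectionModel(
            ("s1", "s2"),
            F=np.array([[0, 2.0], [0, 0]]),
            U=np.array([[0, 0], [0.5, 0]]),
            n_per_stage=np.array([10, 10]),
        )
        table = histories_from_matrix(model)
        s1 = table.initial == 0
        assert np.sum(table.fate[s1] == 1) == 5
        assert np.sum(table.fate[s1] == DEATH) == 5
        assert np.all(table.fate[~s1] == DEATH)
        assert table.recruits[~s1, 0].sum() == 20

    def test_largest_remainder_ties_to_survival(self):
        model = ProjectionModel(
            ("s1", "s2"),
            F=np.zeros((2, 2)),
            U=np.array([[0, 0], [0.5, 0]]),
            n_per_stage=np.array([3, 0]),
        )
        table = histories_from_matrix(model)
        # 1.5 promote / 1.5 die: the tie goes to survival
        assert np.sum(table.fate == 1) == 2
        assert np.sum(table.fate == DEATH) == 1

    def test_round_trip_identity_on_integer_consistent_models(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            m = rng.integers(2, 4)
            n = rng.integers(2, 8, size=m) * 4  # counts divisible by 4
            U = np.zeros((m, m))
            F = np.zeros((m, m))
            for j in range(m):
                # quarters: guaranteed integer expected counts
                dest = rng.integers(0, m, size=2)
                for d in dest:
                    U[d, j] += 0.25
                F[rng.integers(0, m), j] = rng.integers(0, 3)
            model = ProjectionModel(
                tuple(f"s{i}" for i in range(m)), F=F, U=U, n_per_stage=n
            )
            back = project_matrix(histories_from_matrix(model))
            np.testing.assert_allclose(back.U, model.U, atol=1e-12)
            np.testing.assert_allclose(back.F, model.F, atol=1e-12)
            np.testing.assert_array_equal(back.n_per_stage, n)

    def test_negative_death_probability(self):
        with pytest.raises(ValueError):
            ProjectionModel(
                ("a",), F=np.zeros((1, 1)), U=np.array([[1.2]]), n_per_stage=np.array([5])
            )


class TestCompositionVector:
    def test_frequencies(self):
        table = make_table([0, 0, 1], [1, 1, DEATH], np.zeros((3, 2)))
        _, P = composition_vector(table)
        np.testing.assert_allclose(sorted(P[0]), [1 / 3, 2 / 3])

    def test_disjoint_support_gives_delta_one(self):
        a = make_table([0, 0], [1, 1], np.zeros((2, 2)), population_id="A")
        b = make_table([0, 0], [DEATH, DEATH], np.zeros((2, 2)), population_id="B")
        _, P = composition_vector([a, b])
        assert 0.5 * np.abs(P[0] - P[1]).sum() == pytest.approx(1.0)

    def test_identical_tables_and_order_invariance(self):
        rng = np.random.default_rng(3)
        n = 30
        init, fate = rng.integers(0, 2, n), rng.integers(-1, 2, n)
        rec = rng.poisson(0.4, size=(n, 2))
        a = make_table(init, fate, rec)
        perm = rng.permutation(n)
        b = make_table(init[perm], fate[perm], rec[perm])
        _, P = composition_vector([a, b])
        np.testing.assert_allclose(P[0], P[1], atol=1e-12)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


def test_largest_remainder_conserves_total():
    rng = np.random.default_rng(31)
    for _ in range(200):
        k = rng.integers(1, 8)
        x = rng.uniform(0, 10, k)
        total = rng.integers(0, 40)
        alloc = largest_remainder(x * total / max(x.sum(), 1e-9), total, np.arange(k))
        assert alloc.sum() == total
        assert np.all(alloc >= 0)


def test_concat_pools_individuals():
    a = make_table([0, 0], [1, 1], np.zeros((2, 2)), population_id="A")
    b = make_table([1], [DEATH], np.zeros((1, 2)), population_id="B")
    pooled = concat_tables([a, b], "A+B")
    assert pooled.n == 3
    with pytest.raises(ValueError, match="stage space"):
        concat_tables([a, make_table([0], [0], np.zeros((1, 3)), stage_names=("x", "y", "z"))], "bad")
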