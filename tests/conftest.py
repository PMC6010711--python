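"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from popcompare import HistoryTable, VitalRateSpec, simulate_table

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def cycle_matrix() -> np.ndarray:
    """Two-stage cycle A = [[0, 2], [0.5, 0]] with λ = 1 (all closed-form)."""
    return np.array([[0.0, 2.0], [0.5, 0.0]])


@pytest.fixture
def base_spec() -> VitalRateSpec:
    """Juvenile/adult life cycle used across the simulation studies."""
    return VitalRateSpec(
        stage_names=("juvenile", "adult"),
        fate_probs=np.array([[0.3, 0.4, 0.3], [0.0, 0.7, 0.3]]),
        recruit_means=np.array([[0.0, 1.2], [0.0, 0.0]]),
        n_per_stage=np.array([25, 25]),
    )


@pytest.fixture
def two_tables(base_spec) -> list[HistoryTable]:
    rng = np.random.default_rng(2024)
    return [
        simulate_table(base_spec, rng, "A"),
        simulate_table(base_spec, rng, "B"),
    ]


def make_table(
    initial,
    fate,
    recruits,
    stage_names=("s1", "s2"),
    population_id="pop",
    **kwargs,
) -> HistoryTable:
    """Small helper to hand-build a HistoryTable from python lists."""
    initial = np.asarray(initial, dtype=np.int64)
    m = len(stage_names)
    rec = np.asarray(recruits, dtype=np.int64)
    if rec.ndim == 1:
        rec = np.column_stack([rec] + [np.zeros_like(rec)] * (m - 1))
    return HistoryTable(
        population_id=population_id,
        stage_names=tuple(stage_names),
        initial=initial,
        fate=np.asarray(fate, dtype=np.int64),
        recruits=rec,
        **kwargs,
    )


def exhaustive_permutation_distribution(tables, statistic_fn):
    """Exact permutation-null distribution by enumerating every allocation.

    ``statistic_fn`` maps a list of per-group index arrays (into the pooled
    individual list) to the statistic value.  Enumerates all unordered
    allocations of the pooled individuals to groups of the original sizes
    (two groups only), weighting each equally — the exact null that
    Monte-Carlo permutation approximates.
    """
    assert len(tables) == 2, "oracle implemented for two groups"
    n1 = tables[0].n
    pooled_n = n1 + tables[1].n
    values = []
    all_idx = set(range(pooled_n))
    for group1 in combinations(range(pooled_n), n1):
        group2 = sorted(all_idx - set(group1))
        values.append(statistic_fn([np.array(group1), np.array(group2)]))
    return np.array(values)
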