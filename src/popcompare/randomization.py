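"""Test statistics and randomization tests for comparing populations.

The null hypothesis is a *common origin*: observed differences among
populations are no larger than expected when individuals (with their life
histories) are allocated to groups at random.  Four statistics cover the
scalar parameters (λ, R0, T) and the probability-vector parameters (stable
stage structure, reproductive value, history composition):

========  =========  =====================================================
label     scope      definition
========  =========  =====================================================
``dw``    pairwise   ``|x1 − x2|``
``dg``    global     ``Σ_i (x_i − x̄)²``
``Dw``    pairwise   ``½ Σ_j |p_1j − p_2j|``  (Keyfitz's Δ)
``Dg``    global     ``1/(2(n−1)) Σ_j Σ_i |p_ij − p̄·j|``
========  =========  =====================================================

``Dw`` and ``Dg`` lie in [0, 1] and coincide for two populations.  All tests
are upper-tail on these nonnegative distance statistics (which folds both
tails), and the p-value is the proportion of permutation replicates strictly
greater than the observed statistic, with no add-one correction and no
multiplicity adjustment — the reporting layer counts the tests performed and
leaves any correction to the user.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .demography import keyfitz_delta, stable_stage_structure
from .engine import (
    SCALAR_PARAMETERS,
    CompiledBasis,
    compile_tables,
    evaluate_parameter,
    strictly_greater,
)
from .histories import HistoryTable, concat_tables, project_matrix
from .resampling import ResamplingPlan, permute_counts

__all__ = [
    "NullDistribution",
    "stat_scalar_pairwise",
    "stat_scalar_global",
    "stat_vector_pairwise",
    "stat_vector_global",
    "randomization_test",
    "planned_comparison",
    "sss_distance_test",
    "UnreliableResultWarning",
]

#: replicate-skip fraction beyond which a result is flagged unreliable
MAX_SKIP_FRACTION = 0.10


class UnreliableResultWarning(UserWarning):
    """Too many replicates had undefined parameter values (e.g. T at λ≈1)."""


@dataclass
class NullDistribution:
    """A randomization-test result: observed statistic, null replicates, p.

    ``p_value`` is the proportion of *valid* replicates strictly greater than
    the observed statistic; ``n_skipped`` counts replicates where the
    parameter was undefined (they enter neither numerator nor denominator).
    """

    statistic: str  # dw | dg | Dw | Dg | keyfitz_delta
    parameter: str
    observed: float
    replicates: np.ndarray
    p_value: float
    n_reps: int
    n_skipped: int = 0
    populations: tuple[str, ...] = ()
    mode: str = "global"
    unreliable: bool = False
    nonorthogonal: bool = False
    label: str = ""

    @property
    def n_valid(self) -> int:
        return self.n_reps - self.n_skipped


def stat_scalar_pairwise(x1: float, x2: float) -> float:
    """``dw = |x1 − x2|``: absolute difference of two scalar parameters."""
    return float(abs(x1 - x2))


def stat_scalar_global(x: Sequence[float]) -> float:
    """``dg = Σ (x_i − x̄)²``: sum of squares across n ≥ 2 populations."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("global statistic needs at least two populations")
    return float(np.sum((x - x.mean()) ** 2))


def stat_vector_pairwise(p1: Sequence[float], p2: Sequence[float]) -> float:
    """``Dw = ½ Σ |p1j − p2j|``: Keyfitz's Δ between two probability vectors."""
    return keyfitz_delta(p1, p2)


def stat_vector_global(P: np.ndarray) -> float:
    """``Dg = 1/(2(n−1)) Σ_j Σ_i |p_ij − p̄·j|`` over n ≥ 2 aligned rows.

    The mean distance of individual populations from the (unweighted) mean
    composition; equals ``Dw`` when n = 2 and lies in [0, 1].
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("global vector statistic needs an n x m matrix, n >= 2")
    n = P.shape[0]
    mean = P.mean(axis=0)
    return float(np.abs(P - mean).sum() / (2.0 * (n - 1)))


def _batch_scalar_pairwise(x: np.ndarray) -> np.ndarray:
    return np.abs(x[:, 0] - x[:, 1])


def _batch_scalar_global(x: np.ndarray) -> np.ndarray:
    return np.sum((x - x.mean(axis=1, keepdims=True)) ** 2, axis=1)


def _batch_vector_pairwise(P: np.ndarray) -> np.ndarray:
    return 0.5 * np.abs(P[:, 0, :] - P[:, 1, :]).sum(axis=1)


def _batch_vector_global(P: np.ndarray) -> np.ndarray:
    n = P.shape[1]
    mean = P.mean(axis=1, keepdims=True)
    return np.abs(P - mean).sum(axis=(1, 2)) / (2.0 * (n - 1))


def _check_comparable(tables: Sequence[HistoryTable]) -> None:
    first = tables[0]
    for t in tables[1:]:
        if t.stage_names != first.stage_names:
            raise ValueError(
                "populations must have the same number of stages (and labels) "
                f"to be compared: {first.stage_names} vs {t.stage_names}"
            )
        if t.reproduction_type != first.reproduction_type:
            raise ValueError("populations must share the reproduction data type")
        if t.sampling != first.sampling:
            raise ValueError("populations must share the sampling design")


def _statistic_label(parameter: str, pairwise: bool) -> str:
    if parameter in SCALAR_PARAMETERS:
        return "dw" if pairwise else "dg"
    return "Dw" if pairwise else "Dg"


def _anon1_replicate_totals(
    basis: CompiledBasis, counts: np.ndarray, tables: Sequence[HistoryTable]
) -> Optional[np.ndarray]:
    """Per-replicate recruit totals, re-credited by reproductive membership."""
    if basis.reproduction_type != "anon1":
        return None
    pooled_totals = np.sum([t.recruit_totals for t in tables], axis=0).astype(float)
    repro = np.isin(basis.initial, list(basis.reproductive_stages))
    n_repro = counts[..., repro].sum(axis=-1).astype(float)  # (..., G)
    pool = np.maximum(n_repro.sum(axis=-1, keepdims=True), 1.0)
    share = n_repro / pool
    return share[..., None] * pooled_totals


def _group_statistics(
    basis: CompiledBasis,
    counts: np.ndarray,  # (B, G, k)
    parameter: str,
    pairwise: bool,
    tables: Sequence[HistoryTable],
) -> np.ndarray:
    """Statistic per replicate from per-group count matrices."""
    B, G, k = counts.shape
    totals = _anon1_replicate_totals(basis, counts, tables)
    flat_totals = None if totals is None else totals.reshape(B * G, -1)
    values = evaluate_parameter(basis, counts.reshape(B * G, k), parameter, flat_totals)
    if parameter in SCALAR_PARAMETERS:
        x = values.reshape(B, G)
        return _batch_scalar_pairwise(x) if pairwise else _batch_scalar_global(x)
    P = values.reshape(B, G, -1)
    return _batch_vector_pairwise(P) if pairwise else _batch_vector_global(P)


def _finalize(
    stats: np.ndarray,
    observed: float,
    *,
    statistic: str,
    parameter: str,
    populations: tuple[str, ...],
    mode: str,
    label: str = "",
) -> NullDistribution:
    valid = np.isfinite(stats)
    n_reps = stats.size
    n_skipped = int(n_reps - valid.sum())
    if n_skipped > MAX_SKIP_FRACTION * n_reps:
        warnings.warn(
            f"{n_skipped}/{n_reps} replicates had an undefined {parameter}; "
            "the p-value is unreliable",
            UnreliableResultWarning,
            stacklevel=3,
        )
    n_valid = max(n_reps - n_skipped, 1)
    p = float(strictly_greater(stats[valid], observed).sum() / n_valid)
    return NullDistribution(
        statistic=statistic,
        parameter=parameter,
        observed=float(observed),
        replicates=stats,
        p_value=p,
        n_reps=n_reps,
        n_skipped=n_skipped,
        populations=populations,
        mode=mode,
        unreliable=n_skipped > MAX_SKIP_FRACTION * n_reps,
        label=label,
    )


def randomization_test(
    tables: Sequence[HistoryTable],
    parameter: str,
    plan: Optional[ResamplingPlan] = None,
    mode: str = "global",
    pair: Optional[tuple[int, int]] = None,
) -> NullDistribution:
    """Randomization test of a common origin for ≥ 2 populations.

    The observed statistic is computed from the real tables; each replicate
    pools all individuals, reallocates them without replacement to groups of
    the original sizes (stratified by stage under fixed designs) and
    recomputes the statistic.  ``mode="pairwise"`` with ``pair=(i, j)``
    restricts the test to two populations and uses the pairwise statistic.
    """
    plan = plan or ResamplingPlan()
    if mode == "pairwise":
        i, j = pair if pair is not None else (0, 1)
        tables = [tables[i], tables[j]]
    elif mode != "global":
        raise ValueError(f"unknown mode {mode!r}")
    if len(tables) < 2:
        raise ValueError("need at least two populations")
    _check_comparable(tables)
    pairwise = mode == "pairwise"
    # All four statistics are symmetric in the groups; fixing a canonical
    # group order makes results invariant to how the user listed populations
    # (identical random streams feed identical group slices).
    tables = sorted(tables, key=lambda t: (t.population_id, t.n))
    basis, counts = compile_tables(tables)

    obs_totals = (
        np.vstack([t.recruit_totals for t in tables]).astype(float)
        if basis.reproduction_type == "anon1"
        else None
    )
    obs_values = evaluate_parameter(basis, counts, parameter, obs_totals)
    if parameter in SCALAR_PARAMETERS:
        if not np.all(np.isfinite(obs_values)):
            bad = [tables[g].population_id for g in np.nonzero(~np.isfinite(obs_values))[0]]
            raise ValueError(
                f"{parameter} is undefined for population(s) {bad}; "
                "it cannot be used as a comparison parameter here"
            )
        observed = (
            stat_scalar_pairwise(*obs_values) if pairwise else stat_scalar_global(obs_values)
        )
    else:
        observed = (
            stat_vector_pairwise(obs_values[0], obs_values[1])
            if pairwise
            else stat_vector_global(obs_values)
        )

    rng = plan.rng()
    stratified = plan.stratified_permutation and (
        plan.resolve_design(tables[0].sampling) == "fixed_per_stage"
    )
    perm = permute_counts(basis, counts, plan.n_reps, rng, stratified=stratified)
    stats = _group_statistics(basis, perm, parameter, pairwise, tables)
    return _finalize(
        stats,
        observed,
        statistic=_statistic_label(parameter, pairwise),
        parameter=parameter,
        populations=tuple(t.population_id for t in tables),
        mode=mode,
    )


def planned_comparison(
    tables: Sequence[HistoryTable],
    contrasts: Sequence[Sequence[Sequence[int]]],
    parameter: str,
    plan: Optional[ResamplingPlan] = None,
) -> list[NullDistribution]:
    """A-priori comparisons among groups of populations.

    Each contrast is a sequence of groups, each group a sequence of indices
    into ``tables``.  Within a contrast the groups must be disjoint; all
    individuals of a group collapse into one pooled population (parameters
    are re-extracted from the pooled data, never averaged).  Contrast sets
    reusing a population across contrasts are allowed and flagged
    nonorthogonal in the results.
    """
    plan = plan or ResamplingPlan()
    used: list[set[int]] = []
    results = []
    for contrast in contrasts:
        flat: list[int] = []
        for group in contrast:
            if not group:
                raise ValueError("every group in a contrast must be nonempty")
            flat.extend(group)
        if len(set(flat)) != len(flat):
            raise ValueError("groups within one contrast must be disjoint")
        used.append(set(flat))
    nonorth = any(a & b for i, a in enumerate(used) for b in used[i + 1 :])
    for contrast in contrasts:
        pooled = [
            concat_tables(
                [tables[i] for i in group],
                population_id="+".join(tables[i].population_id for i in group),
            )
            for group in contrast
        ]
        mode = "pairwise" if len(pooled) == 2 else "global"
        res = randomization_test(pooled, parameter, plan, mode=mode)
        res.nonorthogonal = nonorth
        res.label = " vs ".join(t.population_id for t in pooled)
        results.append(res)
    return results


def sss_distance_test(
    table: HistoryTable, plan: Optional[ResamplingPlan] = None
) -> NullDistribution:
    """Significance of the Keyfitz distance between the observed stage
    distribution and the stable stage structure of the fitted matrix.

    Only meaningful under pure random sampling: when per-stage counts are set
    by the experimenter the observed stage distribution does not estimate the
    population structure, and the distance is refused.  The null is built by
    bootstrapping *under the hypothesis*: each replicate draws stage counts
    multinomially from the fitted stable structure (simulating a random
    sample from a population that truly sits at its SSS), resamples fates
    and reproduction within each stage from the observed histories, re-fits
    the matrix and recomputes the distance between the replicate's stage
    proportions and its own stable structure.  The p-value is the proportion
    of replicate distances strictly greater than the observed one.
    """
    if table.sampling != "random":
        raise ValueError(
            "distance to the stable stage structure requires pure random "
            "sampling; under a fixed-per-stage design the observed stage "
            "distribution is set by the experimenter and the distance is a "
            "meaningless quantity, so it is not calculated"
        )
    plan = plan or ResamplingPlan()
    model = project_matrix(table)
    observed_p = table.n_per_stage / table.n
    observed = keyfitz_delta(observed_p, stable_stage_structure(model.A))

    basis, counts = compile_tables([table])
    rng = plan.rng()
    sss_hat = stable_stage_structure(model.A)
    # Null stage counts: a fresh multinomial sample from the fitted SSS;
    # fates/reproduction bootstrapped within each stage.
    n_star = rng.multinomial(table.n, sss_hat, size=plan.n_reps)
    boot = np.zeros((plan.n_reps, basis.k), dtype=np.int64)
    for j in range(table.m):
        sel = np.nonzero(basis.initial == j)[0]
        n_j = counts[0, sel].sum()
        if sel.size == 0 or n_j == 0:
            continue
        boot[:, sel] = rng.multinomial(n_star[:, j], counts[0, sel] / n_j)
    totals = (
        np.broadcast_to(table.recruit_totals, (plan.n_reps, table.m)).astype(float)
        if table.reproduction_type == "anon1"
        else None
    )
    sss = evaluate_parameter(basis, boot, "sss", totals)
    n_stage = boot @ basis.stage_ind.T
    props = n_stage / np.maximum(n_stage.sum(axis=1, keepdims=True), 1)
    stats = 0.5 * np.abs(props - sss).sum(axis=1)
    return _finalize(
        stats,
        observed,
        statistic="keyfitz_delta",
        parameter="sss_distance",
        populations=(table.population_id,),
        mode="sss_distance",
    )
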