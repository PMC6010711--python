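"""Resampling-based power estimation and sample-size scaling curves.

Power of a comparison test is estimated entirely by resampling:

1. build the null distribution of the test statistic by pooling all
   individuals and reallocating them to groups without replacement
   (permutation), many times;
2. take the critical value leaving out the α-fraction of largest null values
   (the empirical 1−α quantile);
3. build the alternative distribution by resampling each population
   independently *with* replacement (bootstrap), simulating a fresh sample
   from each original population;
4. power is the proportion of alternative statistics strictly larger than
   the critical value.

The sample-size exploration asks *what would happen* if more individuals had
been sampled with identical vital rates: each step inflates every
population's history counts by a further 20% (step k holds 1.2^k times the
original individuals, with the realized history proportions preserved as
closely as integer counts allow) and reruns the test, the power estimate and
the confidence interval.  This is an idealisation — a real larger sample
would, by chance, show a different composition of histories — but it
indicates the sample sizes at which real differences become detectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .engine import compile_tables, strictly_greater
from .histories import HistoryTable, largest_remainder
from .intervals import bootstrap_ci
from .randomization import NullDistribution, _group_statistics, randomization_test
from .resampling import ResamplingPlan, bootstrap_counts, permute_counts

__all__ = [
    "PowerResult",
    "ScalingStep",
    "ScalingCurve",
    "estimate_power",
    "scale_counts",
    "scaling_analysis",
    "step_seeds",
]

GROWTH_FACTOR = 1.2  # each scaling step adds 20% more individuals


@dataclass
class PowerResult:
    """Null and alternative statistic distributions with the power estimate."""

    parameter: str
    statistic: str
    alpha: float
    critical_value: float
    power: float
    observed: float
    null_replicates: np.ndarray
    alternative_replicates: np.ndarray
    n_reps: int
    n_skipped_null: int
    n_skipped_alternative: int
    populations: tuple[str, ...] = ()


@dataclass
class ScalingStep:
    step: int
    factor: float
    n_per_population: tuple[int, ...]
    p_value: float
    power: float
    ci: dict  # level -> (lower, upper) for the tracked CI quantity
    observed: float


@dataclass
class ScalingCurve:
    parameter: str
    alpha: float
    ci_population: str
    ci_parameter: str
    ci_element: Optional[str]
    steps: list[ScalingStep]


def estimate_power(
    tables: Sequence[HistoryTable],
    parameter: str,
    plan: Optional[ResamplingPlan] = None,
    mode: str = "pairwise",
    alpha: float = 0.05,
    pair: Optional[tuple[int, int]] = None,
) -> PowerResult:
    """Estimate the power of a comparison test by permutation + bootstrap.

    The critical value is the empirical 1−α quantile of the permutation-null
    statistics (the value leaving out the α-fraction of largest
    observations); power is the proportion of bootstrap-alternative
    statistics strictly greater than it.  Ties at the critical value count
    as non-rejection.
    """
    plan = plan or ResamplingPlan()
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    # The null distribution and observed statistic come from the ordinary test.
    null = randomization_test(tables, parameter, plan, mode=mode, pair=pair)
    if mode == "pairwise":
        i, j = pair if pair is not None else (0, 1)
        tables = [tables[i], tables[j]]
    null_valid = null.replicates[np.isfinite(null.replicates)]
    critical = float(np.quantile(null_valid, 1.0 - alpha, method="higher"))

    # Same canonical group order as the test, so power is invariant to how
    # the populations were listed.
    tables = sorted(tables, key=lambda t: (t.population_id, t.n))
    basis, counts = compile_tables(tables)
    rng = plan.rng()
    design = plan.resolve_design(tables[0].sampling)
    # Independent bootstrap of each population per replicate: the alternative.
    alt_counts = np.stack(
        [bootstrap_counts(basis, c, plan.n_reps, design, rng) for c in counts],
        axis=1,
    )  # (B, G, k)
    alt_stats = _group_statistics(basis, alt_counts, parameter, mode == "pairwise", tables)
    alt_valid = alt_stats[np.isfinite(alt_stats)]
    power = float(strictly_greater(alt_valid, critical).sum() / max(alt_valid.size, 1))
    return PowerResult(
        parameter=parameter,
        statistic=null.statistic,
        alpha=alpha,
        critical_value=critical,
        power=power,
        observed=null.observed,
        null_replicates=null.replicates,
        alternative_replicates=alt_stats,
        n_reps=plan.n_reps,
        n_skipped_null=null.n_skipped,
        n_skipped_alternative=int(alt_stats.size - alt_valid.size),
        populations=tuple(t.population_id for t in tables),
    )


def scale_counts(table: HistoryTable, factor: float) -> HistoryTable:
    """Inflate a population to ``round(factor · n)`` individuals while
    preserving the realized history composition as closely as possible.

    Each distinct history's count is multiplied by ``factor`` and the results
    are integerized by largest-remainder rounding (ties to the canonical
    history order), so every history proportion moves by less than 1/n.
    """
    if factor < 1:
        raise ValueError("scaling factor must be >= 1")
    basis, counts = compile_tables([table])
    c = counts[0]
    total = int(round(factor * c.sum()))
    scaled = largest_remainder(c * factor, total, tie_order=np.arange(c.size))
    new = basis.expand_counts(scaled, table)
    if table.reproduction_type == "anon1":
        new.recruit_totals = largest_remainder(
            table.recruit_totals * factor,
            int(round(table.recruit_totals.sum() * factor)),
            tie_order=np.arange(table.m),
        )
    return new


def step_seeds(seed: Optional[int], n_steps: int) -> list[np.random.SeedSequence]:
    """Deterministic per-step seed sequences derived from the master seed."""
    return np.random.SeedSequence(seed).spawn(n_steps + 1)


def scaling_analysis(
    tables: Sequence[HistoryTable],
    parameter: str,
    plan: Optional[ResamplingPlan] = None,
    mode: str = "pairwise",
    alpha: float = 0.05,
    n_steps: int = 6,
    pair: Optional[tuple[int, int]] = None,
    ci_population: int = 0,
    ci_parameter: Optional[str] = None,
    ci_element: Optional[int] = None,
    levels: Sequence[float] = (0.95,),
) -> ScalingCurve:
    """p-value, power and CI width at geometrically growing sample sizes.

    Step k analyses every population inflated by ``1.2**k`` (step 0 is the
    original data).  The tracked confidence interval is for ``ci_parameter``
    (default: the comparison parameter) of population ``ci_population``;
    vector parameters require ``ci_element`` (a stage index).
    """
    plan = plan or ResamplingPlan()
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if mode == "pairwise":
        i, j = pair if pair is not None else (0, 1)
        tables = [tables[i], tables[j]]
    ci_parameter = ci_parameter or parameter
    if ci_parameter == "histories":
        ci_parameter = "lambda"
    seeds = step_seeds(plan.seed, n_steps)
    steps = []
    for k in range(n_steps + 1):
        factor = GROWTH_FACTOR**k
        scaled = [scale_counts(t, factor) for t in tables]
        step_plan = ResamplingPlan(
            n_reps=plan.n_reps,
            seed=None,
            design=plan.design,
            stratified_permutation=plan.stratified_permutation,
        )
        step_plan._seq = seeds[k]
        pw = estimate_power(scaled, parameter, step_plan, mode=mode, alpha=alpha)
        null_valid = pw.null_replicates[np.isfinite(pw.null_replicates)]
        p_value = float(
            strictly_greater(null_valid, pw.observed).sum() / max(null_valid.size, 1)
        )
        ci_rep = bootstrap_ci(scaled[ci_population], ci_parameter, step_plan, levels=levels)
        if isinstance(ci_rep, list):
            if ci_element is None:
                raise ValueError("ci_element is required for vector parameters")
            ci_rep = ci_rep[ci_element]
        steps.append(
            ScalingStep(
                step=k,
                factor=factor,
                n_per_population=tuple(t.n for t in scaled),
                p_value=p_value,
                power=pw.power,
                ci=dict(ci_rep.ci),
                observed=pw.observed,
            )
        )
    element_label = (
        tables[0].stage_names[ci_element] if ci_element is not None else None
    )
    return ScalingCurve(
        parameter=parameter,
        alpha=alpha,
        ci_population=tables[ci_population].population_id,
        ci_parameter=ci_parameter,
        ci_element=element_label,
        steps=steps,
    )
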