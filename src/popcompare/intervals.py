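"""Bootstrap confidence intervals and simulated medians.

For each demographic parameter the report gives the observed value, the
simulated (bootstrap) median, and percentile confidence intervals at 90% and
95%.  The percentile method is used throughout: interval endpoints are the
α/2 and 1−α/2 empirical quantiles of the replicate vector, with linear
interpolation between order statistics (numpy's default quantile rule), so
results are bit-reproducible for a given seed.  BCa intervals are a possible
refinement but are not implemented.

Vector parameters (stable stage structure, reproductive value) get one
interval per stage element; the composition of histories is descriptive only
and is not intervalled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .engine import SCALAR_PARAMETERS, compile_tables, evaluate_parameter
from .histories import HistoryTable
from .resampling import ResamplingPlan, bootstrap_counts

__all__ = ["IntervalReport", "bootstrap_ci", "DEFAULT_LEVELS"]

DEFAULT_LEVELS = (0.90, 0.95)


@dataclass
class IntervalReport:
    """Observed value, simulated median and percentile CIs for one quantity."""

    parameter: str
    element: Optional[str]  # stage label for per-element vector reports
    observed: float
    median: float
    ci: dict  # level -> (lower, upper)
    n_reps: int
    n_undefined: int
    unreliable: bool
    replicates: Optional[np.ndarray] = None

    def width(self, level: float = 0.95) -> float:
        lo, hi = self.ci[level]
        return hi - lo


def _report(
    label: str,
    element: Optional[str],
    observed: float,
    reps: np.ndarray,
    levels: Sequence[float],
    keep_replicates: bool,
) -> IntervalReport:
    valid = reps[np.isfinite(reps)]
    n_undefined = reps.size - valid.size
    unreliable = n_undefined > 0.10 * reps.size
    if valid.size == 0:
        ci = {lv: (np.nan, np.nan) for lv in levels}
        median = np.nan
    else:
        ci = {
            lv: tuple(np.quantile(valid, [(1 - lv) / 2, (1 + lv) / 2]))
            for lv in levels
        }
        median = float(np.quantile(valid, 0.5))
    return IntervalReport(
        parameter=label,
        element=element,
        observed=float(observed),
        median=median,
        ci=ci,
        n_reps=reps.size,
        n_undefined=int(n_undefined),
        unreliable=unreliable,
        replicates=reps if keep_replicates else None,
    )


def bootstrap_ci(
    table: HistoryTable,
    parameter: str,
    plan: Optional[ResamplingPlan] = None,
    levels: Sequence[float] = DEFAULT_LEVELS,
    keep_replicates: bool = False,
) -> "IntervalReport | list[IntervalReport]":
    """Percentile bootstrap CIs for one parameter of one population.

    Returns a single :class:`IntervalReport` for scalar parameters and a
    list of per-stage reports for ``sss``/``rv``.  Replicates where the
    parameter is undefined (e.g. T for a resample with λ = 1) are dropped
    from the quantiles and counted; if more than 10% are undefined the
    report is flagged unreliable.
    """
    if parameter == "histories":
        raise ValueError(
            "confidence intervals are not produced for the composition of histories"
        )
    plan = plan or ResamplingPlan()
    basis, counts = compile_tables([table])
    rng = plan.rng()
    design = plan.resolve_design(table.sampling)
    boot = bootstrap_counts(basis, counts[0], plan.n_reps, design, rng)
    totals = (
        np.broadcast_to(table.recruit_totals, (plan.n_reps, table.m)).astype(float)
        if table.reproduction_type == "anon1"
        else None
    )
    obs_totals = (
        table.recruit_totals[None, :].astype(float)
        if table.reproduction_type == "anon1"
        else None
    )
    observed = evaluate_parameter(basis, counts, parameter, obs_totals)
    reps = evaluate_parameter(basis, boot, parameter, totals)
    if parameter in SCALAR_PARAMETERS:
        return _report(parameter, None, observed[0], reps, levels, keep_replicates)
    return [
        _report(parameter, stage, observed[0, j], reps[:, j], levels, keep_replicates)
        for j, stage in enumerate(basis.stage_names)
    ]
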