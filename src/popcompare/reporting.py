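"""Report assembly: descriptive summaries as JSON-able dicts and plain text.

The ``describe`` report gives, per population: the six demographic
parameters (λ, R0, T, stable stage structure, reproductive value, history
composition), sensitivity and elasticity matrices, bootstrap 90%/95%
intervals with simulated medians for everything except the composition of
histories, and — under pure random sampling only — the Keyfitz distance to
the stable stage structure with its randomization p-value.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import __version__ as _version
from .demography import summarize
from .histories import HistoryTable, composition_vector, project_matrix
from .intervals import IntervalReport, bootstrap_ci
from .randomization import NullDistribution, sss_distance_test
from .resampling import ResamplingPlan

__all__ = ["describe", "render_text", "interval_to_dict", "null_to_dict"]


def interval_to_dict(rep: IntervalReport) -> dict:
    return {
        "parameter": rep.parameter,
        "element": rep.element,
        "observed": rep.observed,
        "median": rep.median,
        "ci": {f"{int(lv * 100)}%": [float(lo), float(hi)] for lv, (lo, hi) in rep.ci.items()},
        "n_reps": rep.n_reps,
        "n_undefined": rep.n_undefined,
        "unreliable": rep.unreliable,
    }


def null_to_dict(res: NullDistribution, include_replicates: bool = False) -> dict:
    out = {
        "statistic": res.statistic,
        "parameter": res.parameter,
        "observed": res.observed,
        "p_value": res.p_value,
        "n_reps": res.n_reps,
        "n_skipped": res.n_skipped,
        "populations": list(res.populations),
        "mode": res.mode,
        "unreliable": res.unreliable,
        "nonorthogonal": res.nonorthogonal,
        "label": res.label,
    }
    if include_replicates:
        out["replicates"] = np.asarray(res.replicates).tolist()
    return out


def describe(
    tables: Sequence[HistoryTable],
    plan: Optional[ResamplingPlan] = None,
    parameters: Sequence[str] = ("lambda", "R0", "T", "sss", "rv"),
) -> dict:
    """Full descriptive report for one or more populations."""
    plan = plan or ResamplingPlan()
    basis, P = composition_vector(list(tables))
    report: dict = {
        "popcompare_version": _version,
        "seed": plan.seed,
        "n_reps": plan.n_reps,
        "n_distinct_histories": int(basis.shape[0]),
        "populations": [],
    }
    for g, table in enumerate(tables):
        model = project_matrix(table)
        summ = summarize(model)
        block: dict = {
            "population_id": table.population_id,
            "n": table.n,
            "n_per_stage": table.n_per_stage.tolist(),
            "stages": list(table.stage_names),
            "census": table.census,
            "sampling": table.sampling,
            "reproduction_type": table.reproduction_type,
            "matrix": {
                "F": model.F.tolist(),
                "U": model.U.tolist(),
                "A": model.A.tolist(),
            },
            "parameters": {
                "lambda": summ.lambda_,
                "R0": None if np.isnan(summ.R0) else summ.R0,
                "T": summ.T,
                "T_undefined_reason": summ.T_undefined_reason,
                "sss": summ.sss.tolist(),
                "rv": summ.rv.tolist(),
            },
            "sensitivity": summ.sensitivity.tolist(),
            "elasticity": summ.elasticity.tolist(),
            "history_composition": P[g].tolist(),
            "intervals": [],
        }
        for param in parameters:
            try:
                rep = bootstrap_ci(table, param, plan)
            except ValueError:
                continue
            reps = rep if isinstance(rep, list) else [rep]
            block["intervals"].extend(interval_to_dict(r) for r in reps)
        if table.sampling == "random":
            sss_test = sss_distance_test(table, plan)
            block["sss_distance"] = {
                "observed_structure": (table.n_per_stage / table.n).tolist(),
                "keyfitz_delta": sss_test.observed,
                "p_value": sss_test.p_value,
                "n_reps": sss_test.n_reps,
            }
        else:
            block["sss_distance"] = None
            block["sss_distance_note"] = (
                "per-stage counts are fixed by the sampling design, so the "
                "distance to the stable stage structure is not calculated"
            )
        report["populations"].append(block)
    return report


def _fmt(x) -> str:
    if x is None:
        return "undefined"
    return f"{x:.4f}"


def render_text(report: dict) -> str:
    """Plain-text rendering of a describe report."""
    lines = [f"popcompare {report['popcompare_version']} — descriptive report"]
    lines.append(
        f"seed={report['seed']} reps={report['n_reps']} "
        f"distinct histories={report['n_distinct_histories']}"
    )
    for block in report["populations"]:
        lines.append("")
        lines.append(f"Population {block['population_id']} (n={block['n']})")
        pars = block["parameters"]
        lines.append(
            f"  lambda={_fmt(pars['lambda'])}  R0={_fmt(pars['R0'])}  T={_fmt(pars['T'])}"
        )
        stages = block["stages"]
        lines.append(
            "  SSS: " + "  ".join(f"{s}={v:.4f}" for s, v in zip(stages, pars["sss"]))
        )
        lines.append(
            "  RV:  " + "  ".join(f"{s}={v:.4f}" for s, v in zip(stages, pars["rv"]))
        )
        for rep in block["intervals"]:
            label = rep["parameter"] + (f"[{rep['element']}]" if rep["element"] else "")
            ci95 = rep["ci"].get("95%", [float("nan")] * 2)
            ci90 = rep["ci"].get("90%", [float("nan")] * 2)
            lines.append(
                f"  {label:12s} obs={rep['observed']:.4f} median={rep['median']:.4f} "
                f"90% [{ci90[0]:.4f}, {ci90[1]:.4f}] 95% [{ci95[0]:.4f}, {ci95[1]:.4f}]"
                + ("  (unreliable)" if rep["unreliable"] else "")
            )
        if block.get("sss_distance"):
            d = block["sss_distance"]
            lines.append(
                f"  distance to SSS: Keyfitz delta={d['keyfitz_delta']:.4f} "
                f"p={d['p_value']:.4f}"
            )
        elif block.get("sss_distance_note"):
            lines.append(f"  distance to SSS: not calculated ({block['sss_distance_note']})")
    return "\n".join(lines)
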