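"""Synthetic demographic data from declared vital rates.

Generates populations of individual life histories for simulation studies
(null calibration, power, coverage): every individual draws a fate from its
initial stage's fate distribution (a multinomial over the m destination
stages plus death), and recruit counts are drawn per recruit stage, either
Poisson around a declared mean or a fixed integer.

Census semantics: under a *prebreeding* census reproduction happens at the
start of the interval, so every individual reproduces at its initial stage's
rate regardless of its fate (recruits must merely be alive at the next
census, which the recruit means already discount).  Under a *postbreeding*
census individuals must survive the whole interval and then reproduce at the
rate of the stage they arrive in, so only survivors draw recruits, with
means indexed by their destination stage.

The generator draws identified-parent data; the anonymous variants are
derived by erasing parentage (:func:`anonymize`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .demography import DEATH
from .histories import HistoryTable, RawDataset

__all__ = [
    "VitalRateSpec",
    "implied_matrices",
    "simulate_table",
    "simulate_population",
    "anonymize",
    "perturb_spec",
]


@dataclass(frozen=True)
class VitalRateSpec:
    """Generating vital rates for one synthetic population.

    Parameters
    ----------
    stage_names:
        Ordered stage labels (length m).
    fate_probs:
        m×(m+1) matrix; row j is the fate distribution of a stage-j
        individual over destinations 0..m−1 plus death in the last column.
        Rows must sum to 1.
    recruit_means:
        m×m matrix; entry (i, j) is the mean number of recruits to stage i
        per parent associated with stage j — the parent's initial stage
        under a prebreeding census, its destination stage under
        postbreeding.
    recruit_distribution:
        ``"poisson"`` (default) or ``"fixed"`` (means must be integers).
    n_per_stage:
        Individuals to simulate per initial stage (fixed-per-stage
        sampling), or the expected stage composition scaled to the total
        under random sampling (see ``simulate_table``).
    """

    stage_names: tuple[str, ...]
    fate_probs: np.ndarray
    recruit_means: np.ndarray
    n_per_stage: np.ndarray
    census: str = "prebreeding"
    sampling: str = "random"
    recruit_distribution: str = "poisson"

    def __post_init__(self) -> None:
        m = len(self.stage_names)
        fp = np.asarray(self.fate_probs, dtype=float)
        rm = np.asarray(self.recruit_means, dtype=float)
        n = np.asarray(self.n_per_stage, dtype=np.int64)
        if fp.shape != (m, m + 1):
            raise ValueError(f"fate_probs must be {m}x{m + 1} (destinations + death)")
        if np.any(fp < 0) or not np.allclose(fp.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each fate distribution must be nonnegative and sum to 1")
        if rm.shape != (m, m) or np.any(rm < 0):
            raise ValueError(f"recruit_means must be a nonnegative {m}x{m} matrix")
        if self.recruit_distribution not in ("poisson", "fixed"):
            raise ValueError("recruit_distribution must be 'poisson' or 'fixed'")
        if self.recruit_distribution == "fixed" and not np.allclose(rm, np.rint(rm)):
            raise ValueError("fixed recruit counts must be integers")
        if n.shape != (m,) or np.any(n < 0) or n.sum() == 0:
            raise ValueError("n_per_stage must be nonnegative with a positive total")
        if self.census not in ("prebreeding", "postbreeding"):
            raise ValueError(f"unknown census {self.census!r}")
        if self.sampling not in ("random", "fixed_per_stage"):
            raise ValueError(f"unknown sampling design {self.sampling!r}")
        object.__setattr__(self, "stage_names", tuple(self.stage_names))
        object.__setattr__(self, "fate_probs", fp)
        object.__setattr__(self, "recruit_means", rm)
        object.__setattr__(self, "n_per_stage", n)

    @property
    def m(self) -> int:
        return len(self.stage_names)


def implied_matrices(spec: VitalRateSpec) -> tuple[np.ndarray, np.ndarray]:
    """(F, U) implied by the vital rates: the expected projection model.

    ``u_ij`` is the probability of the j→i transition.  Under prebreeding,
    ``f_ij`` is the stage-j recruit mean directly; under postbreeding it is
    the survival-weighted mean over destinations, Σ_k u_kj · recruit_means[i, k].
    """
    U = spec.fate_probs[:, : spec.m].T.copy()
    if spec.census == "prebreeding":
        F = spec.recruit_means.copy()
    else:
        F = spec.recruit_means @ U
    return F, U


def simulate_table(
    spec: VitalRateSpec,
    rng: "np.random.Generator | int | None" = None,
    population_id: str = "sim",
) -> HistoryTable:
    """Draw one synthetic population of individual histories.

    Under fixed-per-stage sampling exactly ``n_per_stage[j]`` individuals
    start in stage j.  Under random sampling the total n is kept and the
    initial stages are drawn multinomially from the ``n_per_stage``
    proportions, emulating a random sample from a population with that
    structure.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    m = spec.m
    if spec.sampling == "fixed_per_stage":
        counts = spec.n_per_stage
    else:
        total = int(spec.n_per_stage.sum())
        counts = rng.multinomial(total, spec.n_per_stage / spec.n_per_stage.sum())
    initial = np.repeat(np.arange(m), counts)
    n = initial.size
    fate = np.empty(n, dtype=np.int64)
    pos = 0
    for j in range(m):
        n_j = int(counts[j])
        if n_j == 0:
            continue
        draws = rng.choice(m + 1, size=n_j, p=spec.fate_probs[j])
        fate[pos : pos + n_j] = np.where(draws == m, DEATH, draws)
        pos += n_j
    # Reproduction: stage whose fertility applies depends on the census.
    if spec.census == "prebreeding":
        parent_stage = initial
        reproduces = np.ones(n, dtype=bool)
    else:
        parent_stage = np.where(fate == DEATH, 0, fate)
        reproduces = fate != DEATH
    means = spec.recruit_means[:, parent_stage].T  # (n, m)
    means[~reproduces] = 0.0
    if spec.recruit_distribution == "poisson":
        recruits = rng.poisson(means)
    else:
        recruits = np.rint(means).astype(np.int64)
    return HistoryTable(
        population_id=population_id,
        stage_names=spec.stage_names,
        initial=initial,
        fate=fate,
        recruits=recruits,
        reproduction_type="identified",
        census=spec.census,
        sampling=spec.sampling,
    )


def simulate_population(
    spec: VitalRateSpec,
    rng: "np.random.Generator | int | None" = None,
    population_id: str = "sim",
) -> RawDataset:
    """Draw one synthetic population as a raw tabular dataset."""
    import pandas as pd

    table = simulate_table(spec, rng, population_id)
    rows = []
    for k in range(table.n):
        rec = ";".join(
            f"{spec.stage_names[i]}:{c}" for i, c in enumerate(table.recruits[k]) if c
        )
        rows.append(
            {
                "individual_id": f"{population_id}-{k + 1}",
                "population_id": population_id,
                "initial_stage": spec.stage_names[table.initial[k]],
                "final_stage": "DEAD" if table.fate[k] == DEATH else spec.stage_names[table.fate[k]],
                "recruits": rec,
            }
        )
    return RawDataset(
        data=pd.DataFrame(rows),
        stage_names=spec.stage_names,
        reproduction_type="identified",
        census=spec.census,
        sampling=spec.sampling,
    )


def anonymize(table: HistoryTable, reproduction_type: str) -> HistoryTable:
    """Erase parentage information down to the requested reproduction type.

    ``anon3``/``anon2`` keep per-parent recruit counts (the distinction only
    affects which consistency checks apply); ``anon1`` collapses reproduction
    to population-level recruit totals, with every stage that produced a
    recruit declared reproductive.
    """
    if reproduction_type in ("anon2", "anon3"):
        return replace(table, reproduction_type=reproduction_type)
    if reproduction_type != "anon1":
        raise ValueError(f"unknown reproduction type {reproduction_type!r}")
    totals = table.recruits.sum(axis=0)
    repro = tuple(int(j) for j in np.unique(table.initial[table.recruits.any(axis=1)]))
    if not repro:
        repro = (0,)
    return replace(
        table,
        recruits=np.zeros_like(table.recruits),
        reproduction_type="anon1",
        recruit_totals=totals,
        reproductive_stages=repro,
    )


def perturb_spec(
    spec: VitalRateSpec,
    kind: str,
    stage: int,
    target: int,
    delta: float,
) -> VitalRateSpec:
    """A copy of the spec with one vital rate shifted by ``delta``.

    ``kind="fate"`` shifts the probability of the ``stage → target``
    transition, with the death probability absorbing ``−delta`` so the row
    still sums to 1; ``kind="recruit"`` shifts the mean recruits to stage
    ``target`` per stage-``stage`` parent.  Shifts producing a negative
    probability or mean are errors.
    """
    if kind == "fate":
        fp = spec.fate_probs.copy()
        fp[stage, target] += delta
        fp[stage, spec.m] -= delta
        if fp[stage, target] < -1e-12 or fp[stage, target] > 1 + 1e-12 or fp[stage, spec.m] < -1e-12:
            raise ValueError(
                f"shifting fate[{stage},{target}] by {delta} leaves an invalid distribution"
            )
        fp[stage] = np.clip(fp[stage], 0.0, 1.0)
        return replace(spec, fate_probs=fp)
    if kind == "recruit":
        rm = spec.recruit_means.copy()
        rm[target, stage] += delta
        if rm[target, stage] < 0:
            raise ValueError("recruit mean would become negative")
        return replace(spec, recruit_means=rm)
    raise ValueError(f"unknown perturbation kind {kind!r}")
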