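"""Populations as collections of individual life histories.

An individual history spans exactly one projection interval and records the
individual's initial stage, its fate (destination stage or death) and the
recruits it produced, per recruit stage.  A population is a multiset of such
histories; projection matrices are frequency summaries of it, which is what
makes individual-level resampling (bootstrap, permutation) possible.

Reproduction-data types:

``identified`` / ``anon3``
    every recruit is credited to a known parent whose fate is known.
``anon2``
    parents are known but their destination is not; arithmetic is identical
    to ``anon3`` here because fecundity is credited to the parent's *initial*
    stage, but the postbreeding dead-parent consistency check is skipped.
``anon1``
    anonymous reproduction: only population-level recruit totals per recruit
    stage are known, together with the set of reproductive stages.  Histories
    carry no recruit counts; fecundity divides the totals by the number of
    reproductive individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .demography import DEATH, ProjectionModel

__all__ = [
    "IndividualHistory",
    "HistoryTable",
    "RawDataset",
    "histories_from_raw",
    "project_matrix",
    "histories_from_matrix",
    "composition_vector",
    "concat_tables",
    "largest_remainder",
]

REPRODUCTION_TYPES = ("identified", "anon1", "anon2", "anon3")


@dataclass(frozen=True)
class IndividualHistory:
    """One individual's initial stage, fate and recruit production."""

    initial_stage: int
    fate: int  # stage index or DEATH
    recruits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.recruits):
            raise ValueError("recruit counts must be nonnegative")


@dataclass
class HistoryTable:
    """A population of individual histories with its sampling metadata.

    Array-backed: ``initial`` and ``fate`` are integer vectors of length n
    (fate ``DEATH`` = -1) and ``recruits`` is an n×m integer matrix.  Under
    ``anon1`` the per-individual recruit rows are all zero and the
    population-level ``recruit_totals`` vector is authoritative.
    """

    population_id: str
    stage_names: tuple[str, ...]
    initial: np.ndarray
    fate: np.ndarray
    recruits: np.ndarray
    reproduction_type: str = "identified"
    census: str = "prebreeding"
    sampling: str = "random"
    recruit_totals: Optional[np.ndarray] = None  # anon1 only, length m
    reproductive_stages: tuple[int, ...] = ()  # anon1 only

    def __post_init__(self) -> None:
        m = len(self.stage_names)
        self.initial = np.asarray(self.initial, dtype=np.int64)
        self.fate = np.asarray(self.fate, dtype=np.int64)
        self.recruits = np.asarray(self.recruits, dtype=np.int64)
        n = self.initial.shape[0]
        if n == 0:
            raise ValueError(f"population {self.population_id!r} has no individuals")
        if self.fate.shape != (n,) or self.recruits.shape != (n, m):
            raise ValueError("initial, fate and recruits have inconsistent shapes")
        if self.initial.min() < 0 or self.initial.max() >= m:
            raise ValueError("initial stage index out of range")
        if self.fate.min() < DEATH or self.fate.max() >= m:
            raise ValueError("fate must be a stage index or DEATH")
        if self.recruits.min() < 0:
            raise ValueError("recruit counts must be nonnegative")
        if self.reproduction_type not in REPRODUCTION_TYPES:
            raise ValueError(f"unknown reproduction type {self.reproduction_type!r}")
        if self.reproduction_type == "anon1":
            if self.recruits.any():
                raise ValueError(
                    "anon1 (anonymous reproduction) stores recruit totals at the "
                    "population level, not per history"
                )
            if self.recruit_totals is None or not self.reproductive_stages:
                raise ValueError("anon1 requires recruit_totals and reproductive_stages")
            self.recruit_totals = np.asarray(self.recruit_totals, dtype=np.int64)
            if self.recruit_totals.shape != (m,) or self.recruit_totals.min() < 0:
                raise ValueError("recruit_totals must be a nonnegative vector of length m")
        elif self.census == "postbreeding" and self.reproduction_type in ("identified", "anon3"):
            # Under a postbreeding census reproduction happens after survival:
            # a dead parent cannot be credited with recruits.
            dead_with_recruits = (self.fate == DEATH) & self.recruits.any(axis=1)
            if dead_with_recruits.any():
                raise ValueError(
                    f"postbreeding census: {int(dead_with_recruits.sum())} dead "
                    f"individual(s) carry recruits in population {self.population_id!r}"
                )

    @property
    def m(self) -> int:
        return len(self.stage_names)

    @property
    def n(self) -> int:
        return int(self.initial.shape[0])

    @property
    def n_per_stage(self) -> np.ndarray:
        return np.bincount(self.initial, minlength=self.m)

    def history_keys(self) -> np.ndarray:
        """n×(2+m) integer key rows: (initial, fate-order-key, recruits...).

        The fate key maps DEATH after all stage indices so that the canonical
        ordering is: initial stage, then destination stage (death last), then
        the recruit vector lexicographically.
        """
        fate_key = np.where(self.fate == DEATH, self.m, self.fate)
        return np.column_stack([self.initial, fate_key, self.recruits])

    def distinct_histories(self) -> tuple[np.ndarray, np.ndarray]:
        """(unique key rows in canonical order, counts per unique history)."""
        keys = self.history_keys()
        uniq, counts = np.unique(keys, axis=0, return_counts=True)
        return uniq, counts

    def individuals(self) -> list[IndividualHistory]:
        return [
            IndividualHistory(int(i), int(f), tuple(int(r) for r in rec))
            for i, f, rec in zip(self.initial, self.fate, self.recruits)
        ]

    def subset(self, idx: np.ndarray, population_id: Optional[str] = None) -> "HistoryTable":
        """A new table containing the individuals at ``idx`` (with repeats)."""
        totals = self.recruit_totals
        return replace(
            self,
            population_id=population_id or self.population_id,
            initial=self.initial[idx],
            fate=self.fate[idx],
            recruits=self.recruits[idx],
            recruit_totals=totals,
        )


@dataclass
class RawDataset:
    """Raw demographic data: one record per individual plus shared metadata.

    ``data`` columns: individual_id, population_id, initial_stage,
    final_stage (stage label or ``"DEAD"``), recruits (``stage:count`` pairs
    joined by ``;``, empty for none).  ``recruit_totals`` (anon1 only) maps
    population_id → {stage label: total recruits}.
    """

    data: "pd.DataFrame"  # noqa: F821  (pandas imported lazily)
    stage_names: tuple[str, ...]
    reproduction_type: str = "identified"
    census: str = "prebreeding"
    sampling: str = "random"
    reproductive_stages: tuple[str, ...] = ()
    recruit_totals: dict = field(default_factory=dict)


def _parse_recruits(cell: str, stage_index: dict, m: int) -> np.ndarray:
    out = np.zeros(m, dtype=np.int64)
    if cell is None:
        return out
    cell = str(cell).strip()
    if not cell or cell.lower() == "nan":
        return out
    for pair in cell.split(";"):
        pair = pair.strip()
        if not pair:
            continue
        stage, _, count = pair.partition(":")
        stage = stage.strip()
        if stage not in stage_index:
            raise ValueError(f"unknown recruit stage label {stage!r}")
        out[stage_index[stage]] += int(count)
    return out


def histories_from_raw(raw: RawDataset) -> list[HistoryTable]:
    """Build one HistoryTable per population from a raw dataset."""
    stage_index = {s: j for j, s in enumerate(raw.stage_names)}
    m = len(raw.stage_names)
    tables = []
    for pop_id, group in raw.data.groupby("population_id", sort=True):
        n = len(group)
        if n == 0:
            raise ValueError(f"population {pop_id!r} is empty")
        initial = np.empty(n, dtype=np.int64)
        fate = np.empty(n, dtype=np.int64)
        recruits = np.zeros((n, m), dtype=np.int64)
        for k, (_, row) in enumerate(group.iterrows()):
            s0 = str(row["initial_stage"])
            if s0 not in stage_index:
                raise ValueError(f"unknown stage label {s0!r}")
            initial[k] = stage_index[s0]
            s1 = str(row["final_stage"])
            if s1 == "DEAD":
                fate[k] = DEATH
            elif s1 in stage_index:
                fate[k] = stage_index[s1]
            else:
                raise ValueError(f"unknown stage label {s1!r}")
            rec = _parse_recruits(row.get("recruits", ""), stage_index, m)
            if raw.reproduction_type == "anon1" and rec.any():
                raise ValueError(
                    "per-individual recruits reported under anon1 "
                    "(anonymous reproduction declares totals only)"
                )
            recruits[k] = rec
        totals = None
        repro_stages: tuple[int, ...] = ()
        if raw.reproduction_type == "anon1":
            totals = np.zeros(m, dtype=np.int64)
            for stage, count in raw.recruit_totals.get(str(pop_id), {}).items():
                totals[stage_index[str(stage)]] = int(count)
            repro_stages = tuple(stage_index[s] for s in raw.reproductive_stages)
        tables.append(
            HistoryTable(
                population_id=str(pop_id),
                stage_names=raw.stage_names,
                initial=initial,
                fate=fate,
                recruits=recruits,
                reproduction_type=raw.reproduction_type,
                census=raw.census,
                sampling=raw.sampling,
                recruit_totals=totals,
                reproductive_stages=repro_stages,
            )
        )
    if not tables:
        raise ValueError("raw dataset contains no populations")
    return tables


def project_matrix(table: HistoryTable) -> ProjectionModel:
    """Estimate the projection model (F, U, counts) from observed histories.

    ``u_ij`` is the observed frequency of the j→i transition among stage-j
    individuals; ``f_ij`` is total recruits to stage i credited to stage-j
    individuals divided by n_j, with fecundity always credited to the
    parent's stage at the *start* of the interval (the census type governs
    data validity, not the credited column).
    """
    m = table.m
    n_j = table.n_per_stage
    U = np.zeros((m, m))
    alive = table.fate != DEATH
    np.add.at(U, (table.fate[alive], table.initial[alive]), 1.0)
    F = np.zeros((m, m))
    if table.reproduction_type == "anon1":
        n_repro = int(n_j[list(table.reproductive_stages)].sum())
        if table.recruit_totals.any():
            if n_repro == 0:
                raise ValueError(
                    "recruit totals reported but no reproductive individuals observed"
                )
            for j in table.reproductive_stages:
                F[:, j] = table.recruit_totals / n_repro
    else:
        np.add.at(F.T, table.initial, table.recruits.astype(float))
        F = np.where(n_j > 0, F / np.maximum(n_j, 1), 0.0)
    U = np.where(n_j > 0, U / np.maximum(n_j, 1), 0.0)
    # A stage that receives transitions but was never observed leaves its own
    # column unestimated (zero): legal data, but worth flagging.
    receiving = np.zeros(m, dtype=bool)
    receiving[table.fate[alive]] = True
    missing = receiving & (n_j == 0)
    if missing.any():
        names = [table.stage_names[j] for j in np.nonzero(missing)[0]]
        warnings.warn(
            f"stage(s) {names} appear as fates but have no observed individuals; "
            "their matrix columns are set to zero",
            stacklevel=2,
        )
    return ProjectionModel(
        stage_names=table.stage_names,
        F=F,
        U=U,
        census=table.census,
        n_per_stage=n_j,
        sampling=table.sampling,
    )


def largest_remainder(targets: np.ndarray, total: int, tie_order: np.ndarray) -> np.ndarray:
    """Integerize nonnegative quotas so they sum to ``total``.

    Floors each quota and hands the remaining units to the largest fractional
    parts; exact ties are broken by ascending ``tie_order`` rank.
    """
    targets = np.asarray(targets, dtype=float)
    if np.any(targets < -1e-9):
        raise ValueError("negative quota")
    targets = np.clip(targets, 0.0, None)
    base = np.floor(targets + 1e-9).astype(np.int64)
    remainder = int(total - base.sum())
    if remainder < 0:
        # Quotas overshoot total (rounding noise): trim from smallest fractions.
        order = np.lexsort((tie_order, -(targets - base)))
        for idx in order[::-1]:
            if remainder == 0:
                break
            if base[idx] > 0:
                base[idx] -= 1
                remainder += 1
    elif remainder > 0:
        frac = targets - base
        order = np.lexsort((tie_order, -frac))
        base[order[:remainder]] += 1
    return base


def histories_from_matrix(
    model: ProjectionModel, n_per_stage: Optional[Sequence[int]] = None
) -> HistoryTable:
    """Reconstruct an integer population of histories from a projection model.

    For each stage j, n_j individuals are allocated to fates by largest-
    remainder rounding of ``n_j * u_ij`` (death receives the residual
    probability; ties go to survival, then to the lower destination index).
    Recruits to stage i from stage j total ``round(n_j * f_ij)`` and are
    spread as evenly as possible across the stage-j individuals, survivors
    first — anonymous-reproduction semantics.
    """
    if n_per_stage is None:
        n_per_stage = model.n_per_stage
    if n_per_stage is None:
        raise ValueError("individual counts per stage are required")
    n_per_stage = np.asarray(n_per_stage, dtype=np.int64)
    m = model.m
    active = (model.U.sum(axis=0) > 0) | (model.F.sum(axis=0) > 0)
    if np.any(active & (n_per_stage == 0)):
        raise ValueError("a stage with nonzero rates has zero individuals")
    init_parts: list[np.ndarray] = []
    fate_parts: list[np.ndarray] = []
    rec_parts: list[np.ndarray] = []
    for j in range(m):
        n_j = int(n_per_stage[j])
        if n_j == 0:
            continue
        death_p = 1.0 - model.U[:, j].sum()
        if death_p < -1e-9:
            raise ValueError(f"negative implied death probability in column {j}")
        quotas = np.append(n_j * model.U[:, j], n_j * max(death_p, 0.0))
        # Tie order: survival destinations by ascending index, then death.
        alloc = largest_remainder(quotas, n_j, tie_order=np.arange(m + 1))
        fates = np.repeat(np.append(np.arange(m), DEATH), alloc)
        recruits = np.zeros((n_j, m), dtype=np.int64)
        # Survivors first (fates array already lists them first).
        for i in range(m):
            r_total = int(np.rint(n_j * model.F[i, j]))
            if r_total == 0:
                continue
            base, extra = divmod(r_total, n_j)
            recruits[:, i] += base
            recruits[:extra, i] += 1
        init_parts.append(np.full(n_j, j, dtype=np.int64))
        fate_parts.append(fates)
        rec_parts.append(recruits)
    if not init_parts:
        raise ValueError("no individuals to reconstruct (all counts zero)")
    return HistoryTable(
        population_id="reconstructed",
        stage_names=model.stage_names,
        initial=np.concatenate(init_parts),
        fate=np.concatenate(fate_parts),
        recruits=np.vstack(rec_parts),
        reproduction_type="identified",
        census=model.census,
        sampling=model.sampling,
    )


def shared_history_basis(tables: Sequence[HistoryTable]) -> np.ndarray:
    """Union of distinct histories across tables, in canonical order."""
    if not tables:
        raise ValueError("no tables given")
    m = tables[0].m
    for t in tables[1:]:
        if t.m != m or t.stage_names != tables[0].stage_names:
            raise ValueError("tables do not share a stage space")
    keys = np.vstack([t.history_keys() for t in tables])
    uniq = np.unique(keys, axis=0)
    return uniq


def composition_vector(
    tables: Sequence[HistoryTable] | HistoryTable,
) -> tuple[np.ndarray, np.ndarray]:
    """History-composition probability vectors over the shared history basis.

    Returns ``(basis, P)`` where ``basis`` lists the distinct histories in
    canonical order and ``P`` is an n_tables × n_histories matrix of
    frequencies, each row summing to 1.
    """
    if isinstance(tables, HistoryTable):
        tables = [tables]
    basis = shared_history_basis(tables)
    index = {tuple(row): k for k, row in enumerate(basis)}
    P = np.zeros((len(tables), basis.shape[0]))
    for i, t in enumerate(tables):
        uniq, counts = t.distinct_histories()
        for row, c in zip(uniq, counts):
            P[i, index[tuple(row)]] = c
        P[i] /= P[i].sum()
    return basis, P


def concat_tables(tables: Sequence[HistoryTable], population_id: str) -> HistoryTable:
    """Pool populations into one larger population (planned comparisons).

    All individuals collapse into a single group; demographic parameters are
    then extracted from the pooled population, never averaged.
    """
    first = tables[0]
    for t in tables[1:]:
        if t.stage_names != first.stage_names:
            raise ValueError("pooled populations must share the stage space")
        if t.reproduction_type != first.reproduction_type or t.sampling != first.sampling:
            raise ValueError("pooled populations must share data type and design")
    totals = None
    if first.reproduction_type == "anon1":
        totals = np.sum([t.recruit_totals for t in tables], axis=0)
    return HistoryTable(
        population_id=population_id,
        stage_names=first.stage_names,
        initial=np.concatenate([t.initial for t in tables]),
        fate=np.concatenate([t.fate for t in tables]),
        recruits=np.vstack([t.recruits for t in tables]),
        reproduction_type=first.reproduction_type,
        census=first.census,
        sampling=first.sampling,
        recruit_totals=totals,
        reproductive_stages=first.reproductive_stages,
    )
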