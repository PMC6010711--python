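"""Seeded bootstrap and permutation engine honouring the sampling design.

Two resampling schemes, mirrored at two levels of granularity:

* individual level — :func:`bootstrap_sample` and :func:`permutation_split`
  return real :class:`~popcompare.histories.HistoryTable` objects, one
  replicate at a time;
* counts level — :func:`bootstrap_counts` and :func:`permute_counts` produce
  whole blocks of replicates as count matrices over a compiled history basis
  (see :mod:`popcompare.engine`), which the test/interval/power routines use.

Sampling designs: under ``random`` sampling individuals are resampled (or
pooled and reallocated) with no restriction, so stage proportions vary;
under ``fixed_per_stage`` all resampling is stratified by initial stage so
the experimentally fixed per-stage counts are preserved.  Permutations are
stratified under fixed designs for the same reason the bootstrap is; pass
``stratified=False`` for the unrestricted variant.

Reproducibility: every routine takes a :class:`numpy.random.Generator` or a
:class:`ResamplingPlan`; a plan's generator is spawned from its seed via
``SeedSequence`` so identical seeds give bit-identical replicate streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .engine import CompiledBasis
from .histories import HistoryTable, largest_remainder

__all__ = [
    "ResamplingPlan",
    "bootstrap_sample",
    "permutation_split",
    "bootstrap_counts",
    "permute_counts",
]

DEFAULT_N_REPS = 10_000
MIN_RECOMMENDED_REPS = 999


@dataclass
class ResamplingPlan:
    """Number of replicates, master seed and (optional) design override."""

    n_reps: int = DEFAULT_N_REPS
    seed: Optional[int] = None
    design: Optional[str] = None  # None: take the tables' declared design
    stratified_permutation: bool = True
    _seq: np.random.SeedSequence = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_reps < MIN_RECOMMENDED_REPS:
            warnings.warn(
                f"n_reps={self.n_reps} is below the recommended minimum of "
                f"{MIN_RECOMMENDED_REPS}; p-values will be coarse",
                stacklevel=2,
            )
        self._seq = np.random.SeedSequence(self.seed)

    def rng(self) -> np.random.Generator:
        """A fresh generator for one analysis, spawned from the master seed.

        Successive calls return independent child streams, so each stage of a
        multi-part analysis (observed fit, null replicates, alternative
        replicates, ...) consumes its own substream.
        """
        return np.random.default_rng(self._seq.spawn(1)[0])

    def resolve_design(self, table_design: str) -> str:
        return self.design or table_design


def _as_rng(rng: "np.random.Generator | ResamplingPlan | int | None") -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if isinstance(rng, ResamplingPlan):
        return rng.rng()
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# individual-level API


def bootstrap_sample(
    table: HistoryTable,
    rng: "np.random.Generator | ResamplingPlan | int | None" = None,
    design: Optional[str] = None,
) -> HistoryTable:
    """One bootstrap resample of a population, same total size.

    Random design: individuals resampled with replacement, no restriction.
    Fixed-per-stage design: resampling is restricted to each initial stage,
    preserving per-stage counts exactly.
    """
    rng = _as_rng(rng)
    design = design or table.sampling
    n = table.n
    if design == "random":
        idx = rng.integers(0, n, size=n)
    elif design == "fixed_per_stage":
        idx = np.empty(n, dtype=np.int64)
        pos = 0
        for j in range(table.m):
            members = np.nonzero(table.initial == j)[0]
            if members.size == 0:
                continue
            idx[pos : pos + members.size] = rng.choice(members, size=members.size)
            pos += members.size
    else:
        raise ValueError(f"unknown sampling design {design!r}")
    return table.subset(idx)


def _split_anon1_totals(
    tables: Sequence[HistoryTable], groups: list[np.ndarray], pooled: HistoryTable
) -> list[Optional[np.ndarray]]:
    """Re-credit pooled recruit totals proportionally to each group's share of
    reproductive individuals (anonymous reproduction under permutation)."""
    if tables[0].reproduction_type != "anon1":
        return [None] * len(groups)
    repro = list(tables[0].reproductive_stages)
    total = np.sum([t.recruit_totals for t in tables], axis=0).astype(float)
    repro_mask = np.isin(pooled.initial, repro)
    n_repro_pool = max(int(repro_mask.sum()), 1)
    out = []
    for g in groups:
        share = int(repro_mask[g].sum()) / n_repro_pool
        out.append(largest_remainder(total * share, int(round(total.sum() * share)), np.arange(total.size)))
    return out


def permutation_split(
    tables: Sequence[HistoryTable],
    rng: "np.random.Generator | ResamplingPlan | int | None" = None,
    stratified: Optional[bool] = None,
) -> list[HistoryTable]:
    """Pool all individuals and reallocate them, without replacement, to
    groups of the original sizes — one permutation-null replicate.

    Under the fixed-per-stage design the reallocation happens within
    initial-stage strata (each group keeps its per-stage counts); pass
    ``stratified=False`` to force unrestricted allocation.
    """
    if len(tables) < 2:
        raise ValueError("permutation requires at least two populations")
    from .histories import concat_tables

    rng = _as_rng(rng)
    pooled = concat_tables(tables, population_id="pooled")
    if stratified is None:
        stratified = tables[0].sampling == "fixed_per_stage"
    sizes = [t.n for t in tables]
    if stratified:
        group_idx: list[list[np.ndarray]] = [[] for _ in tables]
        for j in range(pooled.m):
            members = np.nonzero(pooled.initial == j)[0]
            if members.size == 0:
                continue
            members = rng.permutation(members)
            pos = 0
            for g, t in enumerate(tables):
                take = int(np.sum(t.initial == j))
                group_idx[g].append(members[pos : pos + take])
                pos += take
        groups = [np.concatenate(parts) if parts else np.empty(0, np.int64) for parts in group_idx]
    else:
        perm = rng.permutation(pooled.n)
        bounds = np.cumsum([0] + sizes)
        groups = [perm[bounds[g] : bounds[g + 1]] for g in range(len(tables))]
    totals = _split_anon1_totals(tables, groups, pooled)
    out = []
    for t, g, tot in zip(tables, groups, totals):
        new = pooled.subset(np.sort(g), population_id=t.population_id)
        new.sampling = t.sampling
        if tot is not None:
            new.recruit_totals = np.asarray(tot, dtype=np.int64)
            new.reproductive_stages = t.reproductive_stages
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# counts-level batched engine


def _bincount2d(codes: np.ndarray, k: int) -> np.ndarray:
    """Row-wise bincount of an integer (B, n) matrix into (B, k)."""
    B = codes.shape[0]
    offsets = (np.arange(B) * k)[:, None]
    flat = np.bincount((codes + offsets).ravel(), minlength=B * k)
    return flat.reshape(B, k)


def bootstrap_counts(
    basis: CompiledBasis,
    counts: np.ndarray,
    n_reps: int,
    design: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_reps, k) bootstrap count matrices for one population.

    Resampling n individuals with replacement is a multinomial draw over the
    distinct-history frequencies — overall under the random design, within
    each initial-stage stratum under fixed_per_stage.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if design == "random":
        return rng.multinomial(n, counts / n, size=n_reps)
    if design != "fixed_per_stage":
        raise ValueError(f"unknown sampling design {design!r}")
    out = np.zeros((n_reps, counts.size), dtype=np.int64)
    for j in range(basis.m):
        sel = np.nonzero(basis.initial == j)[0]
        n_j = int(counts[sel].sum())
        if n_j == 0:
            continue
        out[:, sel] = rng.multinomial(n_j, counts[sel] / n_j, size=n_reps)
    return out


def permute_counts(
    basis: CompiledBasis,
    group_counts: np.ndarray,
    n_reps: int,
    rng: np.random.Generator,
    stratified: bool,
) -> np.ndarray:
    """(n_reps, G, k) permutation-null count matrices.

    Equivalent to pooling all individuals and shuffling them into groups of
    the original sizes (within initial-stage strata when ``stratified``),
    carried out on history codes so whole replicate blocks are produced at
    once.
    """
    group_counts = np.asarray(group_counts, dtype=np.int64)
    G, k = group_counts.shape
    pooled = group_counts.sum(axis=0)
    out = np.zeros((n_reps, G, k), dtype=np.int64)

    def shuffle_block(codes: np.ndarray, sizes: np.ndarray) -> list[np.ndarray]:
        # Shuffle the pooled codes independently per replicate and cut the
        # permuted row into consecutive group blocks.
        n = codes.size
        order = rng.random((n_reps, n)).argsort(axis=1)
        shuffled = codes[order]
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        return [shuffled[:, bounds[g] : bounds[g + 1]] for g in range(sizes.size)]

    if not stratified:
        codes = np.repeat(np.arange(k), pooled)
        sizes = group_counts.sum(axis=1)
        for g, block in enumerate(shuffle_block(codes, sizes)):
            out[:, g, :] = _bincount2d(block, k)
    else:
        stage_counts = np.zeros((G, basis.m), dtype=np.int64)
        for j in range(basis.m):
            stage_counts[:, j] = group_counts[:, basis.initial == j].sum(axis=1)
        for j in range(basis.m):
            sel = np.nonzero(basis.initial == j)[0]
            codes = np.repeat(sel, pooled[sel])
            if codes.size == 0:
                continue
            for g, block in enumerate(shuffle_block(codes, stage_counts[:, j])):
                if block.shape[1]:
                    out[:, g, :] += _bincount2d(block, k)
    return out
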