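"""Vectorised evaluation of demographic parameters over resampled populations.

Bootstrap and permutation replicates of a population differ from the original
only in *how many copies* of each distinct life history they contain.  All
resampling therefore happens on integer count vectors over the shared basis
of distinct histories, and whole blocks of replicates are evaluated at once:
count matrices map linearly to stacked (U, F) matrices, and λ / R0 / stable
structure come from batched LAPACK eigen-solves.  This is mathematically
identical to resampling individuals one table at a time, just far cheaper.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .demography import DEATH
from .histories import HistoryTable, shared_history_basis

__all__ = ["CompiledBasis", "compile_tables", "evaluate_parameter", "strictly_greater"]

SCALAR_PARAMETERS = ("lambda", "R0", "T")
VECTOR_PARAMETERS = ("sss", "rv", "histories")
PARAMETERS = SCALAR_PARAMETERS + VECTOR_PARAMETERS

_REL_TOL = 1e-12


def strictly_greater(values: np.ndarray, reference: float) -> np.ndarray:
    """Strict comparison with a tiny relative guard against float noise."""
    return np.asarray(values) > reference + _REL_TOL * max(1.0, abs(reference))


@dataclass
class CompiledBasis:
    """Shared distinct-history basis with precomputed contribution tensors.

    ``counts @ trans_w.T`` yields unnormalised stacked U matrices (flattened
    m×m, column-major by source stage j: index i*m+j) and likewise for
    fecundity; dividing by per-stage counts gives the estimated rates.
    """

    stage_names: tuple[str, ...]
    basis: np.ndarray  # (k, 2+m) canonical key rows
    initial: np.ndarray  # (k,)
    fate: np.ndarray  # (k,) DEATH = -1
    recruits: np.ndarray  # (k, m)
    stage_ind: np.ndarray  # (m, k) 1 where initial == j
    trans_w: np.ndarray  # (m*m, k)
    fec_w: np.ndarray  # (m*m, k)
    reproduction_type: str
    census: str
    sampling: str
    reproductive_stages: tuple[int, ...]

    @property
    def m(self) -> int:
        return len(self.stage_names)

    @property
    def k(self) -> int:
        return self.basis.shape[0]

    def counts_of(self, table: HistoryTable) -> np.ndarray:
        """Count vector of a table over this basis."""
        index = {tuple(row): h for h, row in enumerate(self.basis)}
        uniq, counts = table.distinct_histories()
        out = np.zeros(self.k, dtype=np.int64)
        for row, c in zip(uniq, counts):
            key = tuple(row)
            if key not in index:
                raise ValueError("table contains a history outside the compiled basis")
            out[index[key]] = c
        return out

    def expand_counts(self, counts: np.ndarray, table: HistoryTable) -> HistoryTable:
        """Materialise a HistoryTable holding ``counts[h]`` copies of history h."""
        counts = np.asarray(counts, dtype=np.int64)
        idx = np.repeat(np.arange(self.k), counts)
        fate = self.fate[idx]
        return HistoryTable(
            population_id=table.population_id,
            stage_names=self.stage_names,
            initial=self.initial[idx],
            fate=fate,
            recruits=self.recruits[idx],
            reproduction_type=table.reproduction_type,
            census=table.census,
            sampling=table.sampling,
            recruit_totals=table.recruit_totals,
            reproductive_stages=table.reproductive_stages,
        )


def compile_tables(tables: Sequence[HistoryTable]) -> tuple[CompiledBasis, np.ndarray]:
    """Compile tables onto their shared history basis.

    Returns the basis and the (n_tables, k) integer count matrix.
    """
    basis_keys = shared_history_basis(tables)
    first = tables[0]
    m = first.m
    k = basis_keys.shape[0]
    initial = basis_keys[:, 0].astype(np.int64)
    fate = np.where(basis_keys[:, 1] == m, DEATH, basis_keys[:, 1]).astype(np.int64)
    recruits = basis_keys[:, 2:].astype(np.int64)

    stage_ind = np.zeros((m, k))
    stage_ind[initial, np.arange(k)] = 1.0

    trans_w = np.zeros((m * m, k))
    alive = fate != DEATH
    trans_w[fate[alive] * m + initial[alive], np.nonzero(alive)[0]] = 1.0

    fec_w = np.zeros((m * m, k))
    for h in range(k):
        j = initial[h]
        fec_w[np.arange(m) * m + j, h] = recruits[h]

    cb = CompiledBasis(
        stage_names=first.stage_names,
        basis=basis_keys,
        initial=initial,
        fate=fate,
        recruits=recruits,
        stage_ind=stage_ind,
        trans_w=trans_w,
        fec_w=fec_w,
        reproduction_type=first.reproduction_type,
        census=first.census,
        sampling=first.sampling,
        reproductive_stages=first.reproductive_stages,
    )
    counts = np.vstack([cb.counts_of(t) for t in tables])
    return cb, counts


def matrices_from_counts(
    basis: CompiledBasis,
    counts: np.ndarray,
    anon1_totals: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stacked (U, F, n_per_stage) estimated from count vectors.

    ``counts`` is (B, k); returns U and F of shape (B, m, m) and stage counts
    (B, m).  Under anon1, ``anon1_totals`` gives per-replicate recruit totals.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    B = counts.shape[0]
    m = basis.m
    n_stage = counts @ basis.stage_ind.T  # (B, m)
    denom = np.maximum(n_stage, 1.0)
    U = (counts @ basis.trans_w.T).reshape(B, m, m) / denom[:, None, :]
    if basis.reproduction_type == "anon1":
        if anon1_totals is None:
            raise ValueError("anon1 populations require recruit totals")
        totals = np.atleast_2d(np.asarray(anon1_totals, dtype=float))
        repro = list(basis.reproductive_stages)
        n_repro = np.maximum(n_stage[:, repro].sum(axis=1), 1.0)
        F = np.zeros((B, m, m))
        for j in repro:
            F[:, :, j] = totals / n_repro[:, None]
    else:
        F = (counts @ basis.fec_w.T).reshape(B, m, m) / denom[:, None, :]
    return U, F, n_stage


def _dominant_real_eig(values: np.ndarray) -> np.ndarray:
    """Largest real eigenvalue per batch row (Perron root for nonnegative A)."""
    re = values.real.copy()
    scale = 1.0 + np.abs(values).max(axis=1, keepdims=True)
    re[np.abs(values.imag) > 1e-9 * scale] = -np.inf
    out = re.max(axis=1)
    return np.where(np.isfinite(out), out, np.nan)


def _batched_lambda(A: np.ndarray) -> np.ndarray:
    return _dominant_real_eig(np.linalg.eigvals(A))


def _batched_dominant_vectors(A: np.ndarray) -> np.ndarray:
    """Right dominant eigenvectors, nonnegative and sum-normalised; (B, m)."""
    values, vectors = np.linalg.eig(A)
    re = values.real.copy()
    scale = 1.0 + np.abs(values).max(axis=1, keepdims=True)
    re[np.abs(values.imag) > 1e-9 * scale] = -np.inf
    idx = re.argmax(axis=1)
    B = A.shape[0]
    w = vectors[np.arange(B), :, idx].real
    w = np.abs(w)
    s = w.sum(axis=1, keepdims=True)
    uniform = np.full_like(w, 1.0 / w.shape[1])
    return np.where(s > 0, w / np.maximum(s, 1e-300), uniform)


def _batched_r0(U: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Dominant eigenvalue of F(I-U)^{-1} per row; NaN where U is not transient."""
    B, m, _ = U.shape
    rho = np.abs(np.linalg.eigvals(U)).max(axis=1)
    ok = rho < 1.0 - 1e-9
    out = np.full(B, np.nan)
    if ok.any():
        I = np.broadcast_to(np.eye(m), (int(ok.sum()), m, m))
        N = np.linalg.solve(np.eye(m) - U[ok], I)
        R = F[ok] @ N
        out[ok] = np.maximum(_batched_lambda(R), 0.0)
    return out


def evaluate_parameter(
    basis: CompiledBasis,
    counts: np.ndarray,
    parameter: str,
    anon1_totals: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Evaluate one demographic parameter for a batch of count vectors.

    Returns shape (B,) for scalar parameters (NaN where undefined, e.g. T at
    λ=1 or R0 with an absorbing survival loop) and (B, d) for vector
    parameters (stage proportions for sss/rv, history frequencies for
    ``"histories"``).
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}; choose from {PARAMETERS}")
    counts = np.atleast_2d(np.asarray(counts, dtype=np.int64))
    if parameter == "histories":
        totals = counts.sum(axis=1, keepdims=True)
        return counts / np.maximum(totals, 1)
    U, F, _ = matrices_from_counts(basis, counts, anon1_totals)
    A = U + F
    if parameter == "lambda":
        return _batched_lambda(A)
    if parameter == "sss":
        return _batched_dominant_vectors(A)
    if parameter == "rv":
        return _batched_dominant_vectors(np.swapaxes(A, 1, 2))
    r0 = _batched_r0(U, F)
    if parameter == "R0":
        return r0
    # T = ln R0 / ln lambda, undefined at replacement or non-positive rates.
    lam = _batched_lambda(A)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lam = np.log(np.where(lam > 0, lam, np.nan))
        log_r0 = np.log(np.where(r0 > 0, r0, np.nan))
        T = log_r0 / log_lam
    T[np.abs(np.nan_to_num(log_lam)) < 1e-12] = np.nan
    return T
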