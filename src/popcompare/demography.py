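"""Deterministic matrix demography for a single stage-structured population.

A population is summarised by a projection matrix ``A = F + U`` where ``U``
holds survival/growth probabilities between stages (column deficits from 1
are deaths) and ``F`` holds expected recruits per individual per projection
interval.  From ``A`` we derive the asymptotic growth rate λ (dominant
eigenvalue), the stable stage structure (right eigenvector), reproductive
values (left eigenvector), sensitivities and elasticities; from ``F`` and
``U`` the net reproductive rate R0 (dominant eigenvalue of ``F @ inv(I-U)``)
and the generation time ``T = ln R0 / ln λ``.

All functions are pure and operate on small dense matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DEATH",
    "ProjectionModel",
    "DemographicSummary",
    "DegenerateEigenstructureWarning",
    "dominant_eigenvalue",
    "stable_stage_structure",
    "reproductive_value",
    "fundamental_matrix",
    "net_reproductive_rate",
    "generation_time",
    "sensitivity_matrix",
    "elasticity_matrix",
    "keyfitz_delta",
    "summarize",
]

#: Fate marker for individuals that die during the projection interval.
DEATH: int = -1

_IMAG_TOL = 1e-9
_ZERO_TOL = 1e-12
_COLSUM_TOL = 1e-9


class DegenerateEigenstructureWarning(UserWarning):
    """Dominant eigenvalue is complex or non-simple; real part / first vector used."""


def _as_square(A: np.ndarray, name: str = "A") -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(A < 0):
        raise ValueError(f"{name} must be elementwise nonnegative")
    return A


@dataclass(frozen=True)
class ProjectionModel:
    """Projection matrices plus the sampling metadata needed for inference.

    Parameters
    ----------
    stage_names:
        Ordered stage labels (length m).
    F, U:
        m×m fecundity and transition matrices; ``A = F + U``.
    census:
        ``"prebreeding"`` or ``"postbreeding"``.
    n_per_stage:
        Individuals observed per initial stage.  Comparing populations from
        matrices alone is impossible without these counts.
    sampling:
        ``"random"`` (stage proportions estimate the structure) or
        ``"fixed_per_stage"`` (per-stage counts set by the experimenter).
    """

    stage_names: tuple[str, ...]
    F: np.ndarray
    U: np.ndarray
    census: str = "prebreeding"
    n_per_stage: Optional[np.ndarray] = None
    sampling: str = "random"

    def __post_init__(self) -> None:
        m = len(self.stage_names)
        F = _as_square(self.F, "F")
        U = _as_square(self.U, "U")
        if F.shape != (m, m) or U.shape != (m, m):
            raise ValueError(
                f"F and U must be {m}x{m} to match {m} stage names; "
                f"got {F.shape} and {U.shape}"
            )
        colsums = U.sum(axis=0)
        bad = np.nonzero(colsums > 1.0 + _COLSUM_TOL)[0]
        if bad.size:
            raise ValueError(
                f"U column(s) {[self.stage_names[j] for j in bad]} sum to "
                f"{colsums[bad]} > 1: negative implied death probability"
            )
        if self.census not in ("prebreeding", "postbreeding"):
            raise ValueError(f"unknown census type {self.census!r}")
        if self.sampling not in ("random", "fixed_per_stage"):
            raise ValueError(f"unknown sampling design {self.sampling!r}")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "U", U)
        if self.n_per_stage is not None:
            n = np.asarray(self.n_per_stage, dtype=int)
            if n.shape != (m,) or np.any(n < 0):
                raise ValueError("n_per_stage must be a nonnegative integer vector of length m")
            object.__setattr__(self, "n_per_stage", n)
        object.__setattr__(self, "stage_names", tuple(self.stage_names))

    @property
    def m(self) -> int:
        return len(self.stage_names)

    @property
    def A(self) -> np.ndarray:
        return self.F + self.U


@dataclass
class DemographicSummary:
    """All derived demographic parameters for one population."""

    lambda_: float
    R0: float
    T: Optional[float]
    T_undefined_reason: Optional[str]
    sss: np.ndarray
    rv: np.ndarray
    sensitivity: np.ndarray
    elasticity: np.ndarray
    keyfitz_to_sss: Optional[float] = None
    observed_structure: Optional[np.ndarray] = field(default=None)


def _dominant_index(eigvals: np.ndarray) -> int:
    """Index of the dominant eigenvalue among a spectrum.

    For nonnegative matrices the Perron root is real and equals the spectral
    radius; we pick the eigenvalue of maximum real part among those that are
    numerically real, warning if the winner is complex or tied.
    """
    real_mask = np.abs(eigvals.imag) < _IMAG_TOL * max(1.0, np.abs(eigvals).max())
    if real_mask.any():
        candidates = np.nonzero(real_mask)[0]
        idx = candidates[np.argmax(eigvals.real[candidates])]
    else:
        idx = int(np.argmax(eigvals.real))
        warnings.warn(
            "dominant eigenvalue is complex; using its real part",
            DegenerateEigenstructureWarning,
            stacklevel=3,
        )
    dom = eigvals[idx]
    # Multiplicity of the dominant root itself (a periodic matrix's complex
    # eigenvalues of equal modulus do not disturb the Perron vector).
    ties = np.sum(np.abs(eigvals - dom) < 1e-9 * max(1.0, abs(dom)))
    if ties > 1:
        warnings.warn(
            "dominant eigenvalue is not simple (reducible matrix); "
            "results use the first dominant eigenvector",
            DegenerateEigenstructureWarning,
            stacklevel=3,
        )
    return int(idx)


def dominant_eigenvalue(A: np.ndarray) -> float:
    """Asymptotic growth rate λ: the dominant eigenvalue of ``A``."""
    A = _as_square(A)
    eigvals = np.linalg.eigvals(A)
    return float(eigvals[_dominant_index(eigvals)].real)


def _dominant_pair(A: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """(λ, w, v): dominant eigenvalue with right and left eigenvectors."""
    A = _as_square(A)
    eigvals, right = np.linalg.eig(A)
    idx = _dominant_index(eigvals)
    lam = float(eigvals[idx].real)
    w = right[:, idx].real.copy()
    # Left eigenvectors of A are right eigenvectors of A.T for the same λ.
    eigvals_l, left = np.linalg.eig(A.T)
    idx_l = int(np.argmin(np.abs(eigvals_l - eigvals[idx])))
    v = left[:, idx_l].real.copy()
    return lam, _clean_direction(w, A), _clean_direction(v, A)


def _clean_direction(x: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Rescale an eigenvector so its entries are nonnegative; zero tiny noise."""
    if x.sum() < 0:
        x = -x
    x = x.copy()
    x[np.abs(x) < _ZERO_TOL * max(1.0, np.abs(x).max())] = 0.0
    if np.any(x < 0):
        # Mixed signs: only possible for degenerate spectra; fall back to |x|.
        warnings.warn(
            "dominant eigenvector has mixed signs; absolute values used",
            DegenerateEigenstructureWarning,
            stacklevel=4,
        )
        x = np.abs(x)
    return x


def _normalized_or_uniform(x: np.ndarray) -> np.ndarray:
    s = x.sum()
    if s <= 0:
        # Degenerate tie case (e.g. A = I): no preferred direction, return uniform.
        return np.full(x.shape, 1.0 / x.size)
    return x / s


def stable_stage_structure(A: np.ndarray) -> np.ndarray:
    """Stable stage structure: right dominant eigenvector as stage proportions."""
    A = _as_square(A)
    eigvals = np.linalg.eigvals(A)
    if _is_degenerate_identity_like(A, eigvals):
        return np.full(A.shape[0], 1.0 / A.shape[0])
    _, w, _ = _dominant_pair(A)
    return _normalized_or_uniform(w)


def reproductive_value(A: np.ndarray) -> np.ndarray:
    """Reproductive value: left dominant eigenvector as proportional contributions."""
    A = _as_square(A)
    eigvals = np.linalg.eigvals(A)
    if _is_degenerate_identity_like(A, eigvals):
        return np.full(A.shape[0], 1.0 / A.shape[0])
    _, _, v = _dominant_pair(A)
    return _normalized_or_uniform(v)


def _is_degenerate_identity_like(A: np.ndarray, eigvals: np.ndarray) -> bool:
    """All eigenvalues equal and A diagonal: any vector is dominant (tie case)."""
    if not np.allclose(A, np.diag(np.diag(A))):
        return False
    d = np.diag(A)
    return bool(np.allclose(d, d[0]))


def fundamental_matrix(U: np.ndarray) -> np.ndarray:
    """Expected times spent in each stage: ``N = (I - U)^{-1}``.

    Requires spectral radius of ``U`` strictly below 1 (no immortal stages).
    """
    U = _as_square(U, "U")
    rho = np.max(np.abs(np.linalg.eigvals(U)))
    if rho >= 1 - 1e-12:
        colsums = U.sum(axis=0)
        j = int(np.argmax(colsums))
        raise ValueError(
            f"spectral radius of U is {rho:.6g} >= 1 (immortal individuals); "
            f"check column {j} (sum {colsums[j]:.6g})"
        )
    return np.linalg.inv(np.eye(U.shape[0]) - U)


def net_reproductive_rate(F: np.ndarray, U: np.ndarray) -> float:
    """Net reproductive rate R0: dominant eigenvalue of ``R = F N``."""
    F = _as_square(F, "F")
    N = fundamental_matrix(U)
    R = F @ N
    with warnings.catch_warnings():
        # Nilpotent R (cyclic life cycle with no self-recruitment) is legal: R0=0.
        warnings.simplefilter("ignore", DegenerateEigenstructureWarning)
        r0 = dominant_eigenvalue(R)
    return max(r0, 0.0)


def generation_time(lambda_: float, R0: float) -> tuple[Optional[float], Optional[str]]:
    """Generation time ``T = ln R0 / ln λ`` (time to grow by a factor R0).

    Returns ``(T, None)`` when defined, ``(None, reason)`` otherwise — a
    population at replacement (λ = 1) is legal data, not an error.
    """
    if lambda_ <= 0:
        return None, f"lambda={lambda_:.6g} is not positive"
    if R0 <= 0:
        return None, f"R0={R0:.6g} is not positive"
    if abs(np.log(lambda_)) < 1e-12:
        return None, "lambda=1 (population at replacement): ln(lambda)=0"
    return float(np.log(R0) / np.log(lambda_)), None


def sensitivity_matrix(A: np.ndarray) -> np.ndarray:
    """Sensitivities ``s_ij = v_i w_j / <v, w>``: dλ per unit change in a_ij."""
    _, w, v = _dominant_pair(A)
    denom = float(v @ w)
    if abs(denom) < 1e-300:
        raise ValueError("left and right dominant eigenvectors are orthogonal")
    return np.outer(v, w) / denom


def elasticity_matrix(A: np.ndarray) -> np.ndarray:
    """Elasticities ``e_ij = (a_ij / λ) s_ij``: proportional response of λ.

    Entries sum to 1 whenever λ > 0.
    """
    A = _as_square(A)
    lam = dominant_eigenvalue(A)
    if lam <= 0:
        raise ValueError(f"elasticities undefined for lambda={lam:.6g} <= 0")
    return (A / lam) * sensitivity_matrix(A)


def keyfitz_delta(p: Sequence[float], q: Sequence[float]) -> float:
    """Keyfitz's Δ between two probability vectors: ``½ Σ|p_j − q_j|``.

    0 when the vectors are identical, 1 when their supports are disjoint.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError(
            f"probability vectors must have identical length "
            f"(same number of stages); got {p.shape} and {q.shape}"
        )
    for name, x in (("p", p), ("q", q)):
        if np.any(x < -1e-12) or abs(x.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} is not a probability vector (sum {x.sum():.12g})")
    return float(0.5 * np.abs(p - q).sum())


def summarize(model: ProjectionModel) -> DemographicSummary:
    """Compute every demographic parameter for one population.

    The Keyfitz distance between observed stage proportions and the stable
    stage structure is only meaningful under pure random sampling; for
    fixed-per-stage designs it is left absent.
    """
    A = model.A
    lam, w, v = _dominant_pair(A)
    sss = _normalized_or_uniform(w)
    rv = _normalized_or_uniform(v)
    try:
        R0 = net_reproductive_rate(model.F, model.U)
        T, reason = generation_time(lam, R0)
    except ValueError as exc:
        # e.g. an estimated stage with survival 1 (spectral radius of U = 1):
        # expected lifetime diverges, so R0 and T are undefined for this fit.
        R0 = float("nan")
        T, reason = None, str(exc)
    sens = sensitivity_matrix(A)
    elas = (A / lam) * sens if lam > 0 else np.full_like(A, np.nan)

    keyfitz = None
    observed = None
    if model.n_per_stage is not None and model.n_per_stage.sum() > 0:
        observed = model.n_per_stage / model.n_per_stage.sum()
        if model.sampling == "random":
            keyfitz = keyfitz_delta(observed, sss)
    return DemographicSummary(
        lambda_=lam,
        R0=R0,
        T=T,
        T_undefined_reason=reason,
        sss=sss,
        rv=rv,
        sensitivity=sens,
        elasticity=elas,
        keyfitz_to_sss=keyfitz,
        observed_structure=observed,
    )
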