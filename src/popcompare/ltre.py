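"""One-way life table response experiments (LTRE).

LTREs decompose observed variation in the growth rate λ among populations
into contributions from individual matrix entries, weighted by the
sensitivity of λ to each entry.

Fixed design (treatments are the populations of interest themselves)::

    λ(m) − λ(ref)  ≈  Σ_ij (a_ij(m) − a_ij(ref)) · s_ij

with the sensitivities evaluated at the matrix midway between A(m) and the
reference (by default the grand mean matrix Ā; a designated control
population may be used instead).  The first-order residual
λ(m) − λ(ref) − Σ c_ij(m) is reported per population.

Random design (populations are a random sample of environments)::

    V(λ)  ≈  Σ_ij Σ_kl cov(a_ij, a_kl) · s_ij · s_kl

with covariances taken across populations (denominator n−1) and the
sensitivities evaluated at the mean matrix; the per-entry contribution
Σ_kl cov(a_ij, a_kl) s_ij s_kl is reported, and the contributions sum to
the V(λ) approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .demography import ProjectionModel, dominant_eigenvalue, sensitivity_matrix

__all__ = ["LTREResult", "ltre_fixed", "ltre_random"]


@dataclass
class LTREResult:
    """Contribution decomposition for a one-way LTRE."""

    design: str  # "fixed" | "random"
    reference: np.ndarray  # mean (or control) matrix
    lambda_reference: float
    lambdas: np.ndarray  # per-population λ
    contributions: np.ndarray  # fixed: (n, m, m); random: (m, m)
    residuals: Optional[np.ndarray] = None  # fixed only, per population
    variance_lambda: Optional[float] = None  # random only
    population_ids: tuple[str, ...] = ()


def _check_models(models: Sequence[ProjectionModel], minimum: int) -> np.ndarray:
    if len(models) < minimum:
        raise ValueError(f"need at least {minimum} populations")
    m = models[0].m
    for mod in models[1:]:
        if mod.m != m:
            raise ValueError("all populations must have the same number of stages")
    return np.stack([mod.A for mod in models])


def ltre_fixed(
    models: Sequence[ProjectionModel],
    reference: Optional[int] = None,
) -> LTREResult:
    """Fixed-design one-way LTRE.

    ``reference`` selects a control population by index; by default the
    elementwise mean matrix Ā is the reference.  Contributions for
    population m are ``c_ij = (a_ij(m) − ref_ij) · s_ij`` with sensitivities
    at the midpoint matrix ``½(A(m) + ref)``.
    """
    A = _check_models(models, 2)
    ref = A[reference] if reference is not None else A.mean(axis=0)
    lam_ref = dominant_eigenvalue(ref)
    lambdas = np.array([dominant_eigenvalue(a) for a in A])
    contributions = np.empty_like(A)
    for g, a in enumerate(A):
        S = sensitivity_matrix(0.5 * (a + ref))
        contributions[g] = (a - ref) * S
    residuals = lambdas - lam_ref - contributions.sum(axis=(1, 2))
    return LTREResult(
        design="fixed",
        reference=ref,
        lambda_reference=lam_ref,
        lambdas=lambdas,
        contributions=contributions,
        residuals=residuals,
        population_ids=tuple(f"pop{i}" for i in range(len(models))),
    )


def ltre_random(models: Sequence[ProjectionModel]) -> LTREResult:
    """Random-design one-way LTRE: first-order variance decomposition of λ.

    Requires ≥ 3 populations so the covariance matrix has at least two
    degrees of freedom.
    """
    A = _check_models(models, 3)
    n, m, _ = A.shape
    mean = A.mean(axis=0)
    S = sensitivity_matrix(mean)
    flat = A.reshape(n, m * m)
    cov = np.cov(flat, rowvar=False, ddof=1)  # (m², m²)
    s = S.ravel()
    weighted = cov * np.outer(s, s)
    per_entry = weighted.sum(axis=1).reshape(m, m)
    V = float(weighted.sum())
    return LTREResult(
        design="random",
        reference=mean,
        lambda_reference=dominant_eigenvalue(mean),
        lambdas=np.array([dominant_eigenvalue(a) for a in A]),
        contributions=per_entry,
        variance_lambda=V,
        population_ids=tuple(f"pop{i}" for i in range(n)),
    )
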