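"""Eigen-analysis and derived demographic parameters."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from popcompare import (
    dominant_eigenvalue,
    elasticity_matrix,
    fundamental_matrix,
    generation_time,
    keyfitz_delta,
    net_reproductive_rate,
    reproductive_value,
    sensitivity_matrix,
    stable_stage_structure,
)
from popcompare.demography import ProjectionModel, summarize

GOLDEN = (1 + np.sqrt(3)) / 2  # root of x^2 - x - 1/2


@pytest.mark.parametrize(
    "A, expected",
    [
        ([[1, 1], [0.5, 0]], GOLDEN),
        (np.eye(2), 1.0),
        ([[0, 2], [0.5, 0]], 1.0),
        ([[0, 4], [0.5, 0]], np.sqrt(2.0)),
    ],
)
def test_dominant_eigenvalue_closed_forms(A, expected):
    assert dominant_eigenvalue(A) == pytest.approx(expected, abs=1e-10)


def test_dominant_eigenvalue_rejects_bad_input():
    with pytest.raises(ValueError):
        dominant_eigenvalue([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError):
        dominant_eigenvalue([[1, -0.1], [0, 1]])


def test_stable_structure_and_reproductive_value(cycle_matrix):
    np.testing.assert_allclose(stable_stage_structure(cycle_matrix), [2 / 3, 1 / 3], atol=1e-10)
    np.testing.assert_allclose(reproductive_value(cycle_matrix), [1 / 3, 2 / 3], atol=1e-10)
    np.testing.assert_allclose(stable_stage_structure(np.diag([2.0, 1.0])), [1, 0], atol=1e-10)
    np.testing.assert_allclose(reproductive_value(np.diag([2.0, 1.0])), [1, 0], atol=1e-10)
    # Degenerate tie case: the identity has no preferred direction.
    np.testing.assert_allclose(stable_stage_structure(np.eye(2)), [0.5, 0.5])


@pytest.mark.parametrize(
    "U, N",
    [
        ([[0, 0], [0.5, 0]], [[1, 0], [0.5, 1]]),
        (np.zeros((2, 2)), np.eye(2)),
        ([[0.5, 0], [0, 0]], [[2, 0], [0, 1]]),
    ],
)
def test_fundamental_matrix(U, N):
    np.testing.assert_allclose(fundamental_matrix(U), N, atol=1e-12)


def test_fundamental_matrix_immortal_stage_is_an_error():
    with pytest.raises(ValueError, match="spectral radius"):
        fundamental_matrix([[1.0, 0], [0, 0]])


@pytest.mark.parametrize(
    "F, U, R0",
    [
        ([[0, 2], [0, 0]], [[0, 0], [0.5, 0]], 1.0),
        (np.zeros((2, 2)), [[0, 0], [0.5, 0]], 0.0),
        ([[0, 4], [0, 0]], [[0, 0], [0.5, 0]], 2.0),
    ],
)
def test_net_reproductive_rate(F, U, R0):
    assert net_reproductive_rate(F, U) == pytest.approx(R0, abs=1e-10)


def test_generation_time():
    assert generation_time(2, 2) == (pytest.approx(1.0), None)
    assert generation_time(2, 4) == (pytest.approx(2.0), None)
    T, reason = generation_time(1.0, 1.0)
    assert T is None and "replacement" in reason


def test_sensitivity_closed_form(cycle_matrix):
    np.testing.assert_allclose(
        sensitivity_matrix(cycle_matrix), [[0.5, 0.25], [1.0, 0.5]], atol=1e-10
    )
    S = sensitivity_matrix(np.diag([2.0, 1.0]))
    assert S[0, 0] == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(S[np.triu_indices(2, 1)], 0, atol=1e-10)


def test_sensitivity_matches_finite_differences():
    rng = np.random.default_rng(7)
    for _ in range(20):
        m = rng.integers(2, 6)
        A = rng.uniform(0.05, 2.0, size=(m, m))
        S = sensitivity_matrix(A)
        eps = 1e-6
        for i in range(m):
            for j in range(m):
                Ap, Am = A.copy(), A.copy()
                Ap[i, j] += eps
                Am[i, j] -= eps
                fd = (dominant_eigenvalue(Ap) - dominant_eigenvalue(Am)) / (2 * eps)
                assert S[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)


def test_elasticity_closed_form_and_identity(cycle_matrix):
    np.testing.assert_allclose(
        elasticity_matrix(cycle_matrix), [[0, 0.5], [0.5, 0]], atol=1e-10
    )
    rng = np.random.default_rng(11)
    for _ in range(1000):
        m = rng.integers(2, 5)
        A = rng.uniform(0.01, 3.0, size=(m, m))
        E = elasticity_matrix(A)
        assert abs(E.sum() - 1.0) < 1e-8
        assert np.all(E[A == 0] == 0)


def test_eigenvector_equations_hold():
    rng = np.random.default_rng(13)
    for _ in range(200):
        m = rng.integers(2, 6)
        A = rng.uniform(0.05, 2.0, size=(m, m))
        lam = dominant_eigenvalue(A)
        w = stable_stage_structure(A)
        v = reproductive_value(A)
        np.testing.assert_allclose(A @ w, lam * w, atol=1e-8)
        np.testing.assert_allclose(v @ A, lam * v, atol=1e-8)
        assert w.sum() == pytest.approx(1.0, abs=1e-10)
        assert v.sum() == pytest.approx(1.0, abs=1e-10)


def test_lambda_power_T_equals_R0():
    # By construction T = ln R0 / ln lambda, so lambda**T must recover R0.
    rng = np.random.default_rng(17)
    for _ in range(100):
        m = rng.integers(2, 5)
        U = rng.uniform(0, 0.9, size=(m, m))
        U /= np.maximum(U.sum(axis=0), 1.0) * 1.1
        F = rng.uniform(0, 2.0, size=(m, m))
        lam = dominant_eigenvalue(F + U)
        R0 = net_reproductive_rate(F, U)
        T, reason = generation_time(lam, R0)
        if T is not None:
            assert lam**T == pytest.approx(R0, abs=1e-8)


prob_vectors = st.integers(2, 6).flatmap(
    lambda m: arrays(
        float, m, elements=st.floats(0.0, 1.0, allow_nan=False)
    ).filter(lambda x: x.sum() > 1e-6)
)


@given(prob_vectors, prob_vectors, prob_vectors)
def test_keyfitz_is_a_metric(p, q, r):
    size = min(len(p), len(q), len(r))

    def norm(x):
        x = x[:size] + 1e-12
        return x / x.sum()

    p, q, r = norm(p), norm(q), norm(r)
    dpq = keyfitz_delta(p, q)
    assert 0 <= dpq <= 1
    assert dpq == pytest.approx(keyfitz_delta(q, p))
    assert keyfitz_delta(p, p) == 0
    assert dpq <= keyfitz_delta(p, r) + keyfitz_delta(r, q) + 1e-12


@pytest.mark.parametrize(
    "p, q, expected",
    [
        ([0.2, 0.3, 0.5], [0.2, 0.3, 0.5], 0.0),
        ([1, 0], [0, 1], 1.0),
        ([0.5, 0.5], [0.8, 0.2], 0.3),
    ],
)
def test_keyfitz_examples(p, q, expected):
    assert keyfitz_delta(p, q) == pytest.approx(expected, abs=1e-12)


def test_keyfitz_length_mismatch_is_an_error():
    with pytest.raises(ValueError, match="number of stages"):
        keyfitz_delta([1.0, 0.0], [0.5, 0.25, 0.25])


def test_projection_model_validation():
    with pytest.raises(ValueError, match="sum"):
        ProjectionModel(("a", "b"), F=np.zeros((2, 2)), U=np.array([[0.6, 0], [0.6, 0]]))
    model = ProjectionModel(
        ("a", "b"),
        F=np.array([[0, 2.0], [0, 0]]),
        U=np.array([[0, 0], [0.5, 0]]),
        n_per_stage=np.array([10, 10]),
        sampling="fixed_per_stage",
    )
    np.testing.assert_allclose(model.A, [[0, 2], [0.5, 0]])
    summ = summarize(model)
    # Keyfitz distance to SSS is meaningless under a fixed design.
    assert summ.keyfitz_to_sss is None
    assert summ.T is None  # lambda = 1: population at replacement
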