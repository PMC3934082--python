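"""Unit and property tests for the l1-regularized least-squares machinery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sparsemc.sparse_coding import (
    FeatureTransform,
    SolverSettings,
    Vocabulary,
    apply_transform,
    l1_objective,
    normalize_columns,
    solve_l1ls,
)

from _oracles import l1ls_split_oracle
from conftest import random_unit_dictionary


# -- normalize_columns -----------------------------------------------------


def test_normalize_columns_examples():
    M = np.array([[3.0], [4.0]])
    N, s = normalize_columns(M)
    np.testing.assert_allclose(N[:, 0], [0.6, 0.8])
    np.testing.assert_allclose(s, [5.0])

    N, s = normalize_columns(np.eye(3))
    np.testing.assert_allclose(N, np.eye(3))
    np.testing.assert_allclose(s, np.ones(3))

    rng = np.random.default_rng(1)
    M = rng.standard_normal((10, 6))
    N, s = normalize_columns(M)
    np.testing.assert_allclose(np.linalg.norm(N, axis=0), 1.0, atol=1e-12)
    np.testing.assert_allclose(N * s, M)  # scales restore originals


def test_normalize_columns_zero_column_error():
    M = np.ones((3, 4))
    M[:, 2] = 0.0
    with pytest.raises(ValueError, match="2"):
        normalize_columns(M)


@given(hnp.arrays(np.float64, (5, 3), elements=st.floats(-10, 10)))
def test_normalize_round_trip(M):
    norms = np.linalg.norm(M, axis=0)
    if np.any(norms < 1e-6):
        return
    N, s = normalize_columns(M)
    np.testing.assert_allclose(N * s, M, atol=1e-12)


# -- apply_transform -------------------------------------------------------


def test_apply_transform_examples():
    x = np.array([1.0, 2.0, 3.0])
    np.testing.assert_array_equal(apply_transform(FeatureTransform.identity(), x), x)

    down = FeatureTransform.downsample(2)
    np.testing.assert_allclose(apply_transform(down, np.array([1.0, 1.0, 3.0, 3.0])), [1.0, 3.0])

    rng = np.random.default_rng(7)
    tr = FeatureTransform.random_projection(4, 16, seed=7)
    v = rng.standard_normal(16)
    np.testing.assert_allclose(apply_transform(tr, v), tr.matrix @ v)


def test_apply_transform_2d_blocks():
    img = np.arange(16.0).reshape(4, 4)
    tr = FeatureTransform.downsample(2, side=4)
    expected = img.reshape(2, 2, 2, 2).mean(axis=(1, 3)).ravel()
    np.testing.assert_allclose(apply_transform(tr, img.ravel()), expected)


def test_apply_transform_dimension_mismatch():
    tr = FeatureTransform.random_projection(4, 16, seed=0)
    with pytest.raises(ValueError, match="16"):
        apply_transform(tr, np.ones(15))


def test_centering_composes():
    tr = FeatureTransform.downsample(2, center=True)
    out = apply_transform(tr, np.array([1.0, 1.0, 3.0, 3.0]))
    np.testing.assert_allclose(out, [-1.0, 1.0])
    assert abs(out.mean()) < 1e-15


# -- solver: closed forms --------------------------------------------------


def test_orthonormal_soft_threshold():
    code = solve_l1ls(np.eye(2), np.array([1.0, 0.0]), SolverSettings(lam=0.2, gap_tol=1e-10))
    np.testing.assert_allclose(code.coefficients, [0.9, 0.0], atol=1e-7)
    assert code.converged

    # lambda >= 2 max|A'y| forces the zero solution, detected without iterating
    code = solve_l1ls(np.eye(2), np.array([0.3, -0.2]), SolverSettings(lam=1.0))
    np.testing.assert_array_equal(code.coefficients, [0.0, 0.0])
    assert code.iterations == 0 and code.converged


def test_soft_threshold_random_orthonormal(rng):
    Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
    y = rng.standard_normal(6)
    lam = 0.3
    code = solve_l1ls(Q, y, SolverSettings(lam=lam, gap_tol=1e-11, max_iter=2000))
    z = Q.T @ y
    expected = np.sign(z) * np.maximum(np.abs(z) - lam / 2, 0.0)
    np.testing.assert_allclose(code.coefficients, expected, atol=1e-7)


def test_lam_to_zero_recovers_inverse(rng):
    A = rng.standard_normal((4, 4))
    A /= np.linalg.norm(A, axis=0)
    y = rng.standard_normal(4)
    y /= np.linalg.norm(y)
    code = solve_l1ls(A, y, SolverSettings(lam=1e-9, gap_tol=1e-12, max_iter=3000))
    np.testing.assert_allclose(code.coefficients, np.linalg.solve(A, y), atol=1e-4)


# -- solver: oracle equivalence and certificates ---------------------------


def test_solver_matches_split_qp_oracle(rng):
    for _ in range(8):
        d = int(rng.integers(3, 11))
        n = int(rng.integers(4, 21))
        A, y = random_unit_dictionary(rng, d, n)
        lam = float(10 ** rng.uniform(-3, -0.3))
        code = solve_l1ls(A, y, SolverSettings(lam=lam, gap_tol=1e-10, max_iter=3000))
        _, obj_oracle = l1ls_split_oracle(A, y, lam)
        assert code.objective <= obj_oracle + 1e-8
        assert abs(code.objective - obj_oracle) < 1e-6


def test_subgradient_optimality_certificate(rng):
    for _ in range(5):
        A, y = random_unit_dictionary(rng, 8, 15)
        lam = 0.05
        code = solve_l1ls(A, y, SolverSettings(lam=lam, gap_tol=1e-10, max_iter=3000))
        c = code.coefficients
        g = 2 * A.T @ (A @ c - y)
        tol = 1e-4
        on = np.abs(c) > 1e-6
        assert np.all(np.abs(g[~on]) <= lam + tol)
        np.testing.assert_allclose(g[on], -lam * np.sign(c[on]), atol=tol)


def test_l1_norm_monotone_in_lambda(rng):
    A, y = random_unit_dictionary(rng, 8, 12)
    norms = [
        np.abs(solve_l1ls(A, y, SolverSettings(lam=lam, gap_tol=1e-8, max_iter=2000)).coefficients).sum()
        for lam in 10.0 ** np.arange(-4, 1)
    ]
    assert all(a >= b - 1e-6 for a, b in zip(norms, norms[1:]))


# -- objective -------------------------------------------------------------


def test_l1_objective_examples(rng):
    y = np.array([0.6, 0.8])
    assert l1_objective(np.eye(2), y, np.zeros(2), 0.5) == pytest.approx(1.0)
    assert l1_objective(np.eye(2), np.array([1.0, 0.0]), np.array([1.0, 0.0]), 0.5) == pytest.approx(0.5)

    # any candidate code scores no better than the solver's optimum
    A, y = random_unit_dictionary(rng, 6, 10)
    code = solve_l1ls(A, y, SolverSettings(lam=0.1, gap_tol=1e-10, max_iter=2000))
    for _ in range(20):
        c = rng.standard_normal(10) * 0.5
        assert l1_objective(A, y, c, 0.1) >= code.objective - 1e-9


def test_objective_field_is_consistent(rng):
    A, y = random_unit_dictionary(rng, 5, 9)
    code = solve_l1ls(A, y, SolverSettings(lam=0.07))
    recomputed = l1_objective(A, y, code.coefficients, 0.07)
    assert abs(code.objective - recomputed) <= 1e-8 * (1 + abs(recomputed))


# -- error handling and types ----------------------------------------------


def test_solver_error_paths():
    with pytest.raises(ValueError, match="NaN"):
        solve_l1ls(np.eye(2), np.array([np.nan, 0.0]))
    with pytest.raises(ValueError, match="normalized"):
        solve_l1ls(2 * np.eye(2), np.array([1.0, 0.0]))
    code = solve_l1ls(np.eye(2), np.array([1.0, 0.0]), SolverSettings(lam=0.2, max_iter=1, gap_tol=1e-14))
    assert not code.converged  # never silently reported as converged


def test_vocabulary_invariants(tmp_path):
    cols, scales = normalize_columns(np.array([[1.0, 2.0], [2.0, 1.0]]))
    vocab = Vocabulary(cols, [1, -1], normalized=True, scales=scales)
    path = tmp_path / "vocab.npz"
    vocab.save(path)
    back = Vocabulary.load(path)
    np.testing.assert_array_equal(back.columns, vocab.columns)
    np.testing.assert_array_equal(back.labels, vocab.labels)
    np.testing.assert_array_equal(back.scales, vocab.scales)
    assert back.normalized and back.transform_id == "identity"

    with pytest.raises(ValueError, match="both classes"):
        Vocabulary(cols, [1, 1])
    with pytest.raises(ValueError, match="non-unit"):
        Vocabulary(2 * cols, [1, -1], normalized=True)
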