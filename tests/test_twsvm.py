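"""Tests for the twin support vector machine: duals, primal recovery, KKT."""

import numpy as np
import pytest

from sparsemc import twsvm as tw
from sparsemc.synthetic_data import generate_cluster_fixture

from _oracles import enum_box_qp

TOY = dict(A=[[-1.0, 0.0], [-1.0, 1.0]], B=[[1.0, 0.0], [1.0, 1.0]])
LINEAR = tw.KernelSpec("linear")


def _random_problem(rng, c1=None, c2=None):
    d = int(rng.integers(2, 6))
    m1 = int(rng.integers(2, 9))
    m2 = int(rng.integers(2, 9))
    A = rng.standard_normal((m1, d)) - 1.0
    B = rng.standard_normal((m2, d)) + 1.0
    c1 = c1 or float(rng.choice([0.1, 1.0, 10.0]))
    c2 = c2 or float(rng.choice([0.1, 1.0, 10.0]))
    return tw.TWSVMProblem(A=A, B=B, c1=c1, c2=c2, kernel=LINEAR, ridge=1e-6)


def test_build_augmented_appends_ones():
    prob = tw.TWSVMProblem(A=[[1.0, 2.0]], B=[[0.0, 0.0], [1.0, 1.0]], kernel=LINEAR)
    H, G = tw.build_augmented(prob)
    np.testing.assert_array_equal(H, [[1.0, 2.0, 1.0]])
    np.testing.assert_array_equal(G, [[0.0, 0.0, 1.0], [1.0, 1.0, 1.0]])
    assert H.shape[1] == 2 + 1


def test_degenerate_quadratic_terms_saturate_the_box():
    H = np.array([[1.0, 0.0, 1.0]])
    alpha = tw.solve_dtwsvm1(H, np.zeros((3, 3)), c1=2.5)
    np.testing.assert_allclose(alpha, 2.5 * np.ones(3), atol=1e-8)
    gamma = tw.solve_dtwsvm2(np.zeros((2, 3)), np.array([[1.0, 1.0, 1.0]]), c2=4.0)
    np.testing.assert_allclose(gamma, 4.0 * np.ones(2), atol=1e-8)


def test_toy_duals_match_enumeration_oracle():
    prob = tw.TWSVMProblem(**TOY, c1=1.0, c2=1.0, kernel=LINEAR, ridge=1e-6)
    H, G = tw.build_augmented(prob)
    M = tw._ridged(H.T @ H, 1e-6)
    alpha = tw.solve_dtwsvm1(H, G, 1.0, 1e-6)
    np.testing.assert_allclose(alpha, enum_box_qp(G @ np.linalg.solve(M, G.T), np.ones(2), 1.0), atol=1e-5)
    N = tw._ridged(G.T @ G, 1e-6)
    gamma = tw.solve_dtwsvm2(H, G, 1.0, 1e-6)
    np.testing.assert_allclose(gamma, enum_box_qp(H @ np.linalg.solve(N, H.T), np.ones(2), 1.0), atol=1e-5)


def test_rotation_leaves_linear_dual_objective_unchanged(rng):
    prob = _random_problem(rng)
    Q_rot, _ = np.linalg.qr(rng.standard_normal((prob.A.shape[1],) * 2))
    rotated = tw.TWSVMProblem(A=prob.A @ Q_rot, B=prob.B @ Q_rot, c1=prob.c1, c2=prob.c2,
                              kernel=LINEAR, ridge=1e-6)
    obj = tw.train(prob).dual.objective1
    obj_rot = tw.train(rotated).dual.objective1
    assert obj == pytest.approx(obj_rot, abs=1e-6)


def test_recover_primal_identities(rng):
    prob = _random_problem(rng)
    H, G = tw.build_augmented(prob)
    u, v = tw.recover_primal(H, G, np.zeros(G.shape[0]), np.zeros(H.shape[0]), 1e-6)
    np.testing.assert_array_equal(u, 0.0)
    np.testing.assert_array_equal(v, 0.0)

    alpha = rng.uniform(0, 1, G.shape[0])
    gamma = rng.uniform(0, 1, H.shape[0])
    u, v = tw.recover_primal(H, G, alpha, gamma, 1e-6)
    M = tw._ridged(H.T @ H, 1e-6)
    np.testing.assert_allclose(M @ u + G.T @ alpha, 0.0, atol=1e-8)


def test_mirror_symmetric_data_gives_mirror_planes(rng):
    A = rng.standard_normal((6, 3)) + np.array([2.0, 0.0, 0.0])
    prob = tw.TWSVMProblem(A=A, B=-A, c1=2.0, c2=2.0, kernel=LINEAR, ridge=1e-6)
    model = tw.train(prob)
    reflected_u = np.concatenate([model.u[:-1], [-model.u[-1]]])
    np.testing.assert_allclose(model.v, reflected_u, atol=1e-6)


def test_class_swap_symmetry(rng):
    prob = _random_problem(rng, c1=1.0, c2=3.0)
    swapped = tw.TWSVMProblem(A=prob.B, B=prob.A, c1=prob.c2, c2=prob.c1,
                              kernel=LINEAR, ridge=1e-6)
    m1, m2 = tw.train(prob), tw.train(swapped)
    np.testing.assert_allclose(m2.u, -m1.v, atol=1e-6)
    np.testing.assert_allclose(m2.v, -m1.u, atol=1e-6)


def test_separable_gaussians_train_perfectly():
    X, labels = generate_cluster_fixture(((2.0, 0.0), (-2.0, 0.0)), sd=0.3, n=50, seed=3)
    prob = tw.TWSVMProblem(A=X[labels == 1], B=X[labels == -1], c1=10.0, c2=10.0, kernel=LINEAR)
    model = tw.train(prob)
    pred, _ = tw.predict(model, X)
    assert np.array_equal(pred, labels)
    assert model.norm1 > 0 and model.norm2 > 0

    # fresh points go to the nearer cluster mean
    rng = np.random.default_rng(4)
    fresh = rng.uniform(-3, 3, size=(200, 2))
    expect = np.where(np.abs(fresh[:, 0] - 2) <= np.abs(fresh[:, 0] + 2), 1, -1)
    pred, _ = tw.predict(model, fresh)
    assert (pred == expect).mean() > 0.97


def test_more_slack_budget_never_hurts_separable_training_accuracy():
    X, labels = generate_cluster_fixture(((2.0, 0.0), (-2.0, 0.0)), sd=0.3, n=30, seed=6)
    accs = []
    for c in (0.1, 1.0, 10.0, 100.0):
        prob = tw.TWSVMProblem(A=X[labels == 1], B=X[labels == -1], c1=c, c2=c, kernel=LINEAR)
        pred, _ = tw.predict(tw.train(prob), X)
        accs.append((pred == labels).mean())
    assert all(b >= a for a, b in zip(accs, accs[1:]))


def test_predict_distances_and_tie_break():
    model = tw.TWSVMModel(
        u=np.array([1.0, 0.0, 0.0]), v=np.array([0.0, 1.0, 0.0]),
        kernel=LINEAR, reference=None, dual=None, norm1=1.0, norm2=1.0,
    )
    # on plane 1, off plane 2
    lab, margin = tw.predict(model, np.array([0.0, 2.0]))
    assert lab == 1 and margin == pytest.approx(2.0)
    # equidistant -> class +1, margin 0
    lab, margin = tw.predict(model, np.array([1.0, 1.0]))
    assert lab == 1 and margin == 0.0
    with pytest.raises(ValueError, match="dim"):
        tw.predict(model, np.ones(5))


def test_kkt_residual_certifies_trained_models(rng):
    for _ in range(3):
        prob = _random_problem(rng)
        model = tw.train(prob)
        assert tw.kkt_residual(model, prob) <= 1e-5

    # a perturbed (non-optimal) point must violate the conditions
    prob = _random_problem(rng)
    model = tw.train(prob)
    model.u = model.u + 0.5
    model.dual.alpha = np.clip(model.dual.alpha + 0.3, 0, prob.c1)
    assert tw.kkt_residual(model, prob) > 1e-4


def test_interior_multipliers_sit_at_unit_margin():
    X, labels = generate_cluster_fixture(((1.0, 0.0), (-1.0, 0.0)), sd=1.0, n=20, seed=8)
    prob = tw.TWSVMProblem(A=X[labels == 1], B=X[labels == -1], c1=1.0, c2=1.0,
                           kernel=LINEAR, ridge=1e-6)
    model = tw.train(prob)
    H, G = tw.build_augmented(prob)
    alpha = model.dual.alpha
    interior = (alpha > 1e-6) & (alpha < 1.0 - 1e-6)
    assert interior.any()  # overlapping clouds must produce support vectors
    margins = -(G @ model.u)
    np.testing.assert_allclose(margins[interior], 1.0, atol=1e-4)


def test_rbf_mode_and_large_sigma_linear_limit():
    X, labels = generate_cluster_fixture(((2.0, 0.0), (-2.0, 0.0)), sd=0.3, n=30, seed=5)
    X = (X - X.mean(0)) / X.std(0)
    A, B = X[labels == 1], X[labels == -1]
    lin = tw.predict(tw.train(tw.TWSVMProblem(A=A, B=B, c1=10, c2=10, kernel=LINEAR)), X)[0]
    rbf = tw.predict(tw.train(tw.TWSVMProblem(A=A, B=B, c1=10, c2=10,
                                              kernel=tw.KernelSpec("rbf", 30.0))), X)[0]
    assert np.array_equal(lin, rbf)


def test_default_problem_carries_standard_operating_point():
    prob = tw.TWSVMProblem(A=[[0.0]], B=[[1.0]])
    assert prob.kernel.kind == "rbf"
    assert prob.kernel.sigma == 15.0
    assert prob.c1 == prob.c2 == 1000.0


def test_model_round_trip(tmp_path, rng):
    prob = _random_problem(rng)
    prob = tw.TWSVMProblem(A=prob.A, B=prob.B, c1=prob.c1, c2=prob.c2,
                           kernel=tw.KernelSpec("rbf", 2.0), ridge=1e-6)
    model = tw.train(prob)
    model.save(tmp_path / "model.npz")
    back = tw.TWSVMModel.load(tmp_path / "model.npz")
    np.testing.assert_array_equal(back.u, model.u)
    np.testing.assert_array_equal(back.v, model.v)
    np.testing.assert_array_equal(back.reference, model.reference)
    assert back.kernel == model.kernel
    x = rng.standard_normal((4, prob.A.shape[1]))
    np.testing.assert_array_equal(tw.predict(back, x)[1], tw.predict(model, x)[1])


def test_single_class_input_rejected():
    with pytest.raises(ValueError, match="nonempty"):
        tw.TWSVMProblem(A=np.empty((0, 2)), B=[[1.0, 1.0]])
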