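"""Independent oracles used by the test suite.

Each oracle solves the same mathematical problem as the implementation by a
different route: exhaustive active-set enumeration for box QPs, a generic
bound-constrained smooth optimizer on the split reformulation for the
l1-regularized least-squares problem, linear programming for separability,
and a matched filter for phantom learnability.  None of them share code with
the solvers they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import linprog, minimize


def enum_box_qp(Q: np.ndarray, lin: np.ndarray, ub: float) -> np.ndarray:
    """Exact minimizer of 1/2 x'Qx - lin'x over [0, ub]^m by enumerating all
    3^m {lower, free, upper} assignments.  Feasible-and-stationary candidates
    are compared by objective value.  Only for m <= 10."""
    m = len(lin)
    if m > 10:
        raise ValueError("enumeration oracle limited to m <= 10")
    idx = np.arange(m)
    best, best_f = None, np.inf
    for assign in itertools.product((0, 1, 2), repeat=m):
        assign = np.array(assign)
        x = np.where(assign == 2, ub, 0.0)
        free = idx[assign == 1]
        fixed = idx[assign != 1]
        if free.size:
            Qff = Q[np.ix_(free, free)]
            rhs = lin[free] - Q[np.ix_(free, fixed)] @ x[fixed]
            try:
                x[free] = np.linalg.solve(Qff + 1e-13 * np.eye(free.size), rhs)
            except np.linalg.LinAlgError:
                continue
            if np.any(x[free] < -1e-10) or np.any(x[free] > ub + 1e-10):
                continue
        f = 0.5 * x @ Q @ x - lin @ x
        if f < best_f - 1e-14:
            best_f, best = f, x.copy()
    return best


def l1ls_split_oracle(A: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Solve min ||Ac - y||^2 + lam ||c||_1 via the nonnegative split c = p - q
    with a generic bound-constrained quasi-Newton method."""
    n = A.shape[1]
    Ah = np.hstack([A, -A])
    AtA = Ah.T @ Ah
    Aty = Ah.T @ y

    def fg(z):
        r = AtA @ z - 2 * Aty
        f = z @ (AtA @ z) - 2 * Aty @ z + y @ y + lam * z.sum()
        g = 2 * AtA @ z - 2 * Aty + lam
        return f, g

    res = minimize(
        fg, x0=np.zeros(2 * n), jac=True, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * n),
        options={"maxiter": 20000, "ftol": 1e-18, "gtol": 1e-12},
    )
    z = np.maximum(res.x, 0.0)
    c = z[:n] - z[n:]
    obj = float(np.linalg.norm(A @ c - y) ** 2 + lam * np.abs(c).sum())
    return c, obj


def lp_margin(X: np.ndarray, labels: np.ndarray) -> float:
    """Largest t with y_i (w.x_i + b) >= t over ||w||_1 <= 1, by linear
    programming; positive iff the classes are linearly separable."""
    n, d = X.shape
    # variables: wp (d), wn (d), b, t
    c = np.zeros(2 * d + 2)
    c[-1] = -1.0
    A_ub = np.zeros((n + 1, 2 * d + 2))
    b_ub = np.zeros(n + 1)
    for i in range(n):
        A_ub[i, :d] = -labels[i] * X[i]
        A_ub[i, d : 2 * d] = labels[i] * X[i]
        A_ub[i, 2 * d] = -labels[i]
        A_ub[i, -1] = 1.0
    A_ub[n, :2 * d] = 1.0  # sum wp + wn <= 1
    b_ub[n] = 1.0
    bounds = [(0, None)] * (2 * d) + [(None, None), (None, None)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    return float(res.x[-1])


def matched_filter_scores(vectors: np.ndarray, m: int, sigma: float = 2.0) -> np.ndarray:
    """Peak response of a Gaussian-matched filter on mean-removed patches —
    a physics-level detector independent of the sparse-coding pipeline."""
    scores = np.empty(vectors.shape[1])
    for j in range(vectors.shape[1]):
        img = vectors[:, j].reshape(m, m)
        scores[j] = gaussian_filter(img - img.mean(), sigma).max()
    return scores
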