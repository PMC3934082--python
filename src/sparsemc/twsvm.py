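"""Twin support vector machines (TWSVM).

Instead of one maximal-margin hyperplane, a TWSVM fits two nonparallel
planes, each close (in least squares) to its own class and pushed to at
least unit distance from the other, via two small box-constrained dual QPs:

    TWSVM1:  min_u  1/2 ||H u||^2 + c1 e2' q   s.t.  -G u + q >= e2, q >= 0
    TWSVM2:  min_v  1/2 ||G v||^2 + c2 e1' q   s.t.   H v + q >= e1, q >= 0

with H = [A e1], G = [B e2] the augmented pattern matrices (rows = samples)
and u = [w1; b1], v = [w2; b2].  The Wolfe duals are

    DTWSVM1:  max_alpha  e2'alpha - 1/2 alpha' G (H'H)^-1 G' alpha,  0 <= alpha <= c1
    DTWSVM2:  max_gamma  e1'gamma - 1/2 gamma' H (G'G)^-1 H' gamma,  0 <= gamma <= c2

with primal recovery u = -(H'H)^-1 G' alpha and v = +(G'G)^-1 H' gamma (the
sign of v is fixed so class +1 has positive margin with respect to plane 2,
as the TWSVM2 constraint requires).  H'H and G'G are only positive
semidefinite, so the inverses are stabilized by a trace-scaled ridge.  A new
sample is assigned to the class of the nearer plane, distances normalized by
the plane-normal magnitude.

In RBF-kernel mode the same algebra runs on kernel-mapped patterns,
H = [K(A, C') e1], G = [K(B, C') e2] with C = [A; B] the stacked reference
matrix, giving the kernel-generated surfaces K(x', C') w + b = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSpec",
    "TWSVMProblem",
    "DualSolution",
    "TWSVMModel",
    "build_augmented",
    "solve_box_qp",
    "solve_dtwsvm1",
    "solve_dtwsvm2",
    "recover_primal",
    "train",
    "predict",
    "kkt_residual",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel for the plane surfaces: linear, or RBF exp(-||x-z||^2 / (2 sigma^2))."""

    kind: str = "linear"
    sigma: float = 15.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "rbf" and not self.sigma > 0:
            raise ValueError("rbf kernel requires sigma > 0")

    def gram(self, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if self.kind == "linear":
            return X @ Z.T
        d2 = cdist(X, Z, "sqeuclidean")
        return np.exp(-d2 / (2.0 * self.sigma**2))


@dataclass
class TWSVMProblem:
    """Training data (rows = patterns) and hyper-parameters.

    Defaults carry the operating point used throughout the detection
    pipeline: RBF kernel with sigma = 15 and c1 = c2 = 1000.
    """

    A: np.ndarray
    B: np.ndarray
    c1: float = 1000.0
    c2: float = 1000.0
    kernel: KernelSpec = field(default_factory=lambda: KernelSpec("rbf", 15.0))
    ridge: float = 1e-7
    normalize_distance: bool = True

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        if self.A.shape[0] == 0 or self.B.shape[0] == 0:
            raise ValueError("both classes must be nonempty")
        if self.A.shape[1] != self.B.shape[1]:
            raise ValueError("A and B must share the feature dimension")
        if not (self.c1 > 0 and self.c2 > 0):
            raise ValueError("c1 and c2 must be positive")


@dataclass
class DualSolution:
    alpha: np.ndarray
    gamma: np.ndarray
    objective1: float
    objective2: float
    status: str = "ok"


@dataclass
class TWSVMModel:
    """Two trained plane surfaces.

    ``u = [w1; b1]`` and ``v = [w2; b2]`` weigh raw features in linear mode
    and kernel columns against the stacked reference matrix ``C = [A; B]`` in
    RBF mode.  ``norm1``/``norm2`` are the plane-normal magnitudes used to
    turn surface values into distances (kernel-metric norms in RBF mode).
    """

    u: np.ndarray
    v: np.ndarray
    kernel: KernelSpec
    reference: Optional[np.ndarray]
    dual: Optional[DualSolution]
    norm1: float
    norm2: float
    normalize_distance: bool = True

    def save(self, path: Union[str, Path]) -> None:
        from ._io import save_arrays

        save_arrays(
            path,
            u=self.u,
            v=self.v,
            kernel_kind=np.array(self.kernel.kind),
            kernel_sigma=np.array(self.kernel.sigma),
            reference=self.reference if self.reference is not None else np.array([]),
            norm1=np.array(self.norm1),
            norm2=np.array(self.norm2),
            normalize_distance=np.array(self.normalize_distance),
            alpha=self.dual.alpha if self.dual else np.array([]),
            gamma=self.dual.gamma if self.dual else np.array([]),
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TWSVMModel":
        with np.load(path, allow_pickle=False) as f:
            ref = f["reference"]
            alpha, gamma = f["alpha"], f["gamma"]
            dual = (
                DualSolution(alpha=alpha, gamma=gamma, objective1=np.nan, objective2=np.nan)
                if alpha.size
                else None
            )
            return cls(
                u=f["u"],
                v=f["v"],
                kernel=KernelSpec(str(f["kernel_kind"]), float(f["kernel_sigma"])),
                reference=ref if ref.size else None,
                dual=dual,
                norm1=float(f["norm1"]),
                norm2=float(f["norm2"]),
                normalize_distance=bool(f["normalize_distance"]),
            )


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------


def _mapped_patterns(problem: TWSVMProblem) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    if problem.kernel.kind == "linear":
        return problem.A, problem.B, None
    C = np.vstack([problem.A, problem.B])
    return problem.kernel.gram(problem.A, C), problem.kernel.gram(problem.B, C), C


def build_augmented(problem: TWSVMProblem) -> tuple[np.ndarray, np.ndarray]:
    """H = [A e1], G = [B e2] (kernel-mapped patterns in RBF mode)."""
    PA, PB, _ = _mapped_patterns(problem)
    H = np.hstack([PA, np.ones((PA.shape[0], 1))])
    G = np.hstack([PB, np.ones((PB.shape[0], 1))])
    return H, G


def _ridged(M: np.ndarray, ridge: float) -> np.ndarray:
    k = M.shape[0]
    eff = ridge * (1.0 + np.trace(M) / k)
    return M + eff * np.eye(k)


def solve_box_qp(Q: np.ndarray, lin: np.ndarray, ub: float) -> np.ndarray:
    """Minimize ``1/2 x'Qx - lin'x`` over the box ``0 <= x <= ub``.

    L-BFGS-B provides the global phase; an active-set polish then solves the
    free-variable KKT system exactly so the box-projected gradient vanishes
    to solver precision.  Q must be symmetric positive semidefinite.
    """
    Q = 0.5 * (Q + Q.T)
    lin = np.asarray(lin, dtype=float)
    m = lin.shape[0]
    tiny = 1e-12 * (1.0 + np.trace(Q) / m)

    def fg(x):
        g = Q @ x - lin
        return 0.5 * x @ (g - lin), g

    res = minimize(
        fg,
        x0=np.zeros(m),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, ub)] * m,
        options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12},
    )
    x = np.clip(res.x, 0.0, ub)
    fx = fg(x)[0]

    btol = 1e-8 * max(ub, 1.0)
    for _ in range(80):
        g = Q @ x - lin
        low = (x <= btol) & (g >= 0)
        upp = (x >= ub - btol) & (g <= 0)
        free = ~(low | upp)
        xn = np.where(upp, ub, 0.0)
        if free.any():
            Qff = Q[np.ix_(free, free)] + tiny * np.eye(int(free.sum()))
            rhs = lin[free] - Q[np.ix_(free, ~free)] @ xn[~free]
            try:
                xn[free] = cho_solve(cho_factor(Qff, lower=True, check_finite=False), rhs, check_finite=False)
            except np.linalg.LinAlgError:
                xn[free] = np.linalg.lstsq(Qff, rhs, rcond=None)[0]
        xn = np.clip(xn, 0.0, ub)
        fn = fg(xn)[0]
        if fn <= fx:
            moved = not np.allclose(xn, x, rtol=0, atol=1e-14)
            x, fx = xn, fn
            if not moved:
                break
        else:
            break
    return x


def solve_dtwsvm1(H: np.ndarray, G: np.ndarray, c1: float, ridge: float = 1e-7) -> np.ndarray:
    """DTWSVM1: maximize e2'a - 1/2 a' G (H'H)^-1 G' a over 0 <= a <= c1."""
    if not c1 > 0:
        raise ValueError("c1 must be positive")
    M = _ridged(H.T @ H, ridge)
    Q = G @ np.linalg.solve(M, G.T)
    return solve_box_qp(Q, np.ones(G.shape[0]), c1)


def solve_dtwsvm2(H: np.ndarray, G: np.ndarray, c2: float, ridge: float = 1e-7) -> np.ndarray:
    """DTWSVM2: maximize e1'g - 1/2 g' H (G'G)^-1 H' g over 0 <= g <= c2.

    The multiplier vector has one entry per class +1 pattern (row of H), as
    dimensional consistency of the second primal problem requires.
    """
    if not c2 > 0:
        raise ValueError("c2 must be positive")
    N = _ridged(G.T @ G, ridge)
    Q = H @ np.linalg.solve(N, H.T)
    return solve_box_qp(Q, np.ones(H.shape[0]), c2)


def recover_primal(
    H: np.ndarray, G: np.ndarray, alpha: np.ndarray, gamma: np.ndarray, ridge: float = 1e-7
) -> tuple[np.ndarray, np.ndarray]:
    """u = -(H'H + eps I)^-1 G' alpha;  v = +(G'G + eps I)^-1 H' gamma.

    The positive sign of ``v`` orients plane 2 so that class +1 sits on its
    positive side (the KKT stationarity of TWSVM2, G'G v = H' gamma).
    """
    M = _ridged(H.T @ H, ridge)
    N = _ridged(G.T @ G, ridge)
    try:
        u = -cho_solve(cho_factor(M, lower=True, check_finite=False), G.T @ alpha, check_finite=False)
        v = cho_solve(cho_factor(N, lower=True, check_finite=False), H.T @ gamma, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "augmented Gram matrix is singular even with the ridge; increase twsvm.ridge"
        ) from exc
    return u, v


def train(problem: TWSVMProblem) -> TWSVMModel:
    """Solve both duals, recover both planes, and package the model."""
    H, G = build_augmented(problem)
    alpha = solve_dtwsvm1(H, G, problem.c1, problem.ridge)
    gamma = solve_dtwsvm2(H, G, problem.c2, problem.ridge)
    u, v = recover_primal(H, G, alpha, gamma, problem.ridge)

    M = _ridged(H.T @ H, problem.ridge)
    N = _ridged(G.T @ G, problem.ridge)
    Qa = G @ np.linalg.solve(M, G.T)
    Qg = H @ np.linalg.solve(N, H.T)
    obj1 = float(alpha.sum() - 0.5 * alpha @ Qa @ alpha)
    obj2 = float(gamma.sum() - 0.5 * gamma @ Qg @ gamma)

    _, _, C = _mapped_patterns(problem)
    w1, w2 = u[:-1], v[:-1]
    if problem.kernel.kind == "linear":
        norm1 = float(np.linalg.norm(w1))
        norm2 = float(np.linalg.norm(w2))
    else:
        # kernel-metric norm sqrt(w' K(C, C) w) of the surface normal
        KCC = problem.kernel.gram(C, C)
        norm1 = float(np.sqrt(max(w1 @ KCC @ w1, 0.0)))
        norm2 = float(np.sqrt(max(w2 @ KCC @ w2, 0.0)))

    return TWSVMModel(
        u=u,
        v=v,
        kernel=problem.kernel,
        reference=C,
        dual=DualSolution(alpha=alpha, gamma=gamma, objective1=obj1, objective2=obj2),
        norm1=norm1,
        norm2=norm2,
        normalize_distance=problem.normalize_distance,
    )


def _surface_values(model: TWSVMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.kernel.kind == "rbf":
        if model.reference is None:
            raise ValueError("rbf model lacks its reference matrix")
        if X.shape[1] != model.reference.shape[1]:
            raise ValueError(
                f"input dim {X.shape[1]} does not match model raw dim {model.reference.shape[1]}"
            )
        Phi = model.kernel.gram(X, model.reference)
    else:
        if X.shape[1] != model.u.shape[0] - 1:
            raise ValueError(
                f"input dim {X.shape[1]} does not match model dim {model.u.shape[0] - 1}"
            )
        Phi = X
    val1 = Phi @ model.u[:-1] + model.u[-1]
    val2 = Phi @ model.v[:-1] + model.v[-1]
    return val1, val2


def predict(model: TWSVMModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign each sample to the class of the nearer plane.

    Returns ``(labels, margin_scores)`` with ``margin = d2 - d1`` (larger =
    more class +1); a tie goes to class +1.  Scalars are returned for a
    single sample.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    val1, val2 = _surface_values(model, x)
    if model.normalize_distance:
        d1 = np.abs(val1) / max(model.norm1, np.finfo(float).tiny)
        d2 = np.abs(val2) / max(model.norm2, np.finfo(float).tiny)
    else:
        d1, d2 = np.abs(val1), np.abs(val2)
    labels = np.where(d1 <= d2, 1, -1)
    margin = d2 - d1
    if single:
        return int(labels[0]), float(margin[0])
    return labels, margin


def kkt_residual(model: TWSVMModel, problem: TWSVMProblem) -> float:
    """Maximum KKT violation of the trained model on its own problem.

    Checks, for both QPPs: ridged stationarity of the primal recovery, box
    feasibility of the multipliers, dual box-projected-gradient
    stationarity, and complementary slackness with the implied slacks
    q = max(0, e + margin).  Used by tests as an optimality certificate.
    """
    H, G = build_augmented(problem)
    alpha = model.dual.alpha
    gamma = model.dual.gamma
    u, v = model.u, model.v
    M = _ridged(H.T @ H, problem.ridge)
    N = _ridged(G.T @ G, problem.ridge)

    viol = [
        np.max(np.abs(M @ u + G.T @ alpha)),
        np.max(np.abs(N @ v - H.T @ gamma)),
        max(np.max(-alpha), 0.0),
        max(np.max(alpha - problem.c1), 0.0),
        max(np.max(-gamma), 0.0),
        max(np.max(gamma - problem.c2), 0.0),
    ]

    for Q, mult, ub, margins, sign in (
        (G @ np.linalg.solve(M, G.T), alpha, problem.c1, G @ u, -1.0),
        (H @ np.linalg.solve(N, H.T), gamma, problem.c2, H @ v, +1.0),
    ):
        g = Q @ mult - np.ones_like(mult)  # gradient of the minimized dual
        btol = 1e-8 * max(ub, 1.0)
        interior = (mult > btol) & (mult < ub - btol)
        viol.append(np.max(np.abs(g[interior])) if interior.any() else 0.0)
        viol.append(np.max(np.maximum(-g[mult <= btol], 0.0)) if (mult <= btol).any() else 0.0)
        viol.append(np.max(np.maximum(g[mult >= ub - btol], 0.0)) if (mult >= ub - btol).any() else 0.0)
        # primal slack and complementary slackness: constraint sign*margin >= 1 - q
        q = np.maximum(0.0, 1.0 - sign * margins)
        viol.append(abs(mult @ (sign * margins + q - 1.0)) / (1.0 + ub))
        viol.append(abs((ub - mult) @ q) / (1.0 + ub))
    return float(max(viol))
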