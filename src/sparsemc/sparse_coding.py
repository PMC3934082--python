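"""Sparse coding of image patches over a labelled vocabulary.

A test patch ``y`` is expressed as a sparse linear combination of the columns
of a "vocabulary" matrix ``A`` whose columns are vectorized training patches
(both microcalcification and normal-tissue examples).  The coefficient vector
``c`` is the minimizer of the l1-regularized least-squares objective

    J(c, lambda) = ||A c - y||_2^2 + lambda * ||c||_1

which is the standard convex surrogate for the combinatorial sparsest-
representation problem.  The solver is a primal log-barrier interior-point
method on the bound-split reformulation

    minimize  ||A c - y||_2^2 + lambda * 1'u   subject to  -u <= c <= u,

with direct (Cholesky) inner Newton solves and a duality gap computed from a
scaled dual-feasible point, so every returned code carries a certificate of
near-optimality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "Vocabulary",
    "FeatureTransform",
    "SparseCode",
    "SolverSettings",
    "normalize_columns",
    "apply_transform",
    "solve_l1ls",
    "l1_objective",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class FeatureTransform:
    """A linear feature map ``x -> D x`` applied to raw patch vectors.

    Kinds
    -----
    identity
        Returns the input unchanged (``D = I``).
    random_projection
        Dense Gaussian projection matrix, ``D`` of shape ``(d, m)`` with
        ``d < m``; entries scaled by ``1/sqrt(d)``.
    downsample
        Block-mean compression by an integer ``factor``.  With ``side`` set,
        the input is interpreted as a row-major vectorized ``side x side``
        patch and blocks are 2-D ``factor x factor`` tiles; otherwise blocks
        are runs of ``factor`` consecutive entries.

    ``center=True`` additionally removes the mean of the transformed vector,
    i.e. composes ``D`` with the (linear) centering projector ``I - 11'/d``.
    """

    kind: str = "identity"
    matrix: Optional[np.ndarray] = None
    factor: int = 1
    side: Optional[int] = None
    center: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "random_projection", "downsample"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "random_projection":
            if self.matrix is None:
                raise ValueError("random_projection requires a matrix")
            if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[0]:
                raise ValueError("random_projection matrix must have full row rank")

    # -- factories ---------------------------------------------------------

    @classmethod
    def identity(cls, center: bool = False) -> "FeatureTransform":
        return cls(kind="identity", center=center)

    @classmethod
    def random_projection(cls, d: int, m: int, seed: int, center: bool = False) -> "FeatureTransform":
        rng = np.random.default_rng(seed)
        mat = rng.standard_normal((d, m)) / np.sqrt(d)
        return cls(kind="random_projection", matrix=mat, center=center)

    @classmethod
    def downsample(cls, factor: int, side: Optional[int] = None, center: bool = False) -> "FeatureTransform":
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return cls(kind="downsample", factor=factor, side=side, center=center)

    @property
    def id_string(self) -> str:
        parts = [self.kind]
        if self.kind == "downsample":
            parts.append(f"f{self.factor}" + (f"s{self.side}" if self.side else ""))
        if self.kind == "random_projection" and self.matrix is not None:
            parts.append("x".join(map(str, self.matrix.shape)))
        if self.center:
            parts.append("centered")
        return "-".join(parts)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return apply_transform(self, x)


def apply_transform(transform: FeatureTransform, x: np.ndarray) -> np.ndarray:
    """Apply the linear feature map to a vector or to a matrix of columns."""
    x = np.asarray(x, dtype=float)
    vec = x.ndim == 1
    X = x[:, None] if vec else x
    m, ncol = X.shape

    if transform.kind == "identity":
        out = X.copy()
    elif transform.kind == "random_projection":
        D = transform.matrix
        if D.shape[1] != m:
            raise ValueError(
                f"transform of shape {D.shape} cannot be applied to input of length {m}"
            )
        out = D @ X
    else:  # downsample
        f = transform.factor
        if transform.side is not None:
            s = transform.side
            if m != s * s:
                raise ValueError(
                    f"downsample expects vectorized {s}x{s} patches (length {s * s}), got length {m}"
                )
            if s % f:
                raise ValueError(f"side {s} not divisible by factor {f}")
            t = s // f
            blocks = X.T.reshape(ncol, t, f, t, f)
            out = blocks.mean(axis=(2, 4)).reshape(ncol, t * t).T
        else:
            if m % f:
                raise ValueError(f"input length {m} not divisible by factor {f}")
            out = X.T.reshape(ncol, m // f, f).mean(axis=2).T

    if transform.center:
        out = out - out.mean(axis=0, keepdims=True)
    return out[:, 0] if vec else out


def normalize_columns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale every column to unit Euclidean norm.

    Returns the normalized matrix and the original column norms (so the
    originals are recovered exactly as ``normalized * scales``).  An all-zero
    column is an error: silently dropping it would desynchronize the labels.
    """
    matrix = np.asarray(matrix, dtype=float)
    scales = np.linalg.norm(matrix, axis=0)
    bad = np.flatnonzero(scales <= np.finfo(float).tiny ** 0.5)
    if bad.size:
        raise ValueError(f"cannot normalize zero column(s) at index {bad.tolist()}")
    return matrix / scales, scales


@dataclass
class Vocabulary:
    """Column matrix of vectorized training patches with per-column labels.

    ``columns`` is ``d x n`` (one feature column per training sample) and
    ``labels`` holds the binary class of each column, ``+1`` for
    microcalcification patches and ``-1`` for normal tissue.
    """

    columns: np.ndarray
    labels: np.ndarray
    normalized: bool = False
    transform_id: str = "identity"
    scales: Optional[np.ndarray] = None
    _gram: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    def validate(self) -> None:
        if self.columns.ndim != 2:
            raise ValueError("columns must be a 2-D matrix")
        d, n = self.columns.shape
        if d < 1 or n < 2:
            raise ValueError(f"vocabulary needs d >= 1 and n >= 2, got {d}x{n}")
        if self.labels.shape != (n,):
            raise ValueError(f"labels length {self.labels.shape} does not match {n} columns")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be in {+1, -1}")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present in the vocabulary")
        if self.normalized:
            norms = np.linalg.norm(self.columns, axis=0)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("normalized vocabulary has non-unit columns")

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]

    @property
    def dim(self) -> int:
        return self.columns.shape[0]

    def gram(self) -> np.ndarray:
        """Cached ``A'A`` used by repeated sparse-coding solves."""
        if self._gram is None:
            self._gram = self.columns.T @ self.columns
        return self._gram

    # -- serialization (portable npz container) ----------------------------

    def save(self, path: Union[str, Path]) -> None:
        from ._io import save_arrays

        save_arrays(
            path,
            columns=self.columns,
            labels=self.labels,
            normalized=np.array(self.normalized),
            transform_id=np.array(self.transform_id),
            scales=self.scales if self.scales is not None else np.array([]),
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "Vocabulary":
        with np.load(path, allow_pickle=False) as f:
            scales = f["scales"]
            return cls(
                columns=f["columns"],
                labels=f["labels"],
                normalized=bool(f["normalized"]),
                transform_id=str(f["transform_id"]),
                scales=scales if scales.size else None,
            )


@dataclass
class SolverSettings:
    """Knobs of the l1-regularized least-squares solver.

    lam
        Regularization weight lambda > 0 balancing sparsity against
        reconstruction error.
    gap_tol
        Relative duality-gap tolerance: the solver stops once
        ``gap <= gap_tol * (1 + |objective|)``.
    max_iter
        Cap on total Newton steps.
    ridge
        Tiny diagonal added to the inner Newton systems for numerical
        stability.
    """

    lam: float = 0.01
    gap_tol: float = 1e-4
    max_iter: int = 500
    ridge: float = 1e-10

    def __post_init__(self) -> None:
        if not (self.lam > 0 and self.gap_tol > 0 and self.max_iter > 0 and self.ridge > 0):
            raise ValueError("all solver settings must be positive")


@dataclass
class SparseCode:
    """Solution of the l1-regularized least-squares problem.

    ``objective`` is J(c, lambda) at the returned coefficients and
    ``duality_gap`` the certified distance to the optimum; ``converged`` is
    true iff the gap met the configured tolerance.
    """

    coefficients: np.ndarray
    lam: float
    objective: float
    duality_gap: float
    iterations: int
    converged: bool


# --------------------------------------------------------------------------
# objective and solver
# --------------------------------------------------------------------------


def l1_objective(
    vocab: Union[Vocabulary, np.ndarray],
    y: np.ndarray,
    coefficients: np.ndarray,
    lam: float,
) -> float:
    """Evaluate ``||A c - y||_2^2 + lam * ||c||_1`` as a pure function."""
    A = vocab.columns if isinstance(vocab, Vocabulary) else np.asarray(vocab, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(coefficients, dtype=float)
    if A.shape[1] != c.shape[0]:
        raise ValueError(f"A has {A.shape[1]} columns but c has length {c.shape[0]}")
    if A.shape[0] != y.shape[0]:
        raise ValueError(f"A has {A.shape[0]} rows but y has length {y.shape[0]}")
    r = A @ c - y
    return float(r @ r + lam * np.abs(c).sum())


def _duality_gap(lam, l1_c, Atr, rTr, rTy):
    """Gap from the scaled dual-feasible point.

    For P(c) = ||Ac-y||^2 + lam||c||_1 the dual function of the residual
    variable is g(nu) = -||nu||^2/4 + nu'y over ||A'nu||_inf <= lam.  The
    candidate nu = 2(y - Ac) is scaled into the feasible set, giving a valid
    lower bound on the optimum and hence a certificate P - g >= suboptimality.
    """
    primal = rTr + lam * l1_c
    sup = np.max(np.abs(2.0 * Atr)) if Atr.size else 0.0
    s = 1.0 if sup <= lam else lam / sup
    dual = -s * s * rTr + 2.0 * s * rTy
    return primal, max(primal - dual, 0.0)


def solve_l1ls(
    vocab: Union[Vocabulary, np.ndarray],
    y: np.ndarray,
    settings: Optional[SolverSettings] = None,
) -> SparseCode:
    """Solve ``min_c ||A c - y||_2^2 + lam ||c||_1`` by an interior-point method.

    ``vocab`` must have unit-norm columns (the classification algorithm
    normalizes both the vocabulary and the test vector before coding).  The
    solver is deterministic; non-convergence within ``max_iter`` Newton steps
    is reported through ``converged=False``, never silently.
    """
    settings = settings or SolverSettings()
    if isinstance(vocab, Vocabulary):
        A = vocab.columns
        AtA = vocab.gram()
    else:
        A = np.asarray(vocab, dtype=float)
        AtA = A.T @ A
    y = np.asarray(y, dtype=float)
    if A.ndim != 2 or A.shape[0] != y.shape[0]:
        raise ValueError(f"shape mismatch: A is {A.shape}, y has length {y.shape}")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(y))):
        raise ValueError("NaN/Inf in solver inputs")
    norms = np.sqrt(np.diag(AtA))
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("vocabulary columns must be normalized to unit length")

    lam = settings.lam
    n = A.shape[1]
    Aty = A.T @ y
    yTy = float(y @ y)

    c = np.zeros(n)
    u = np.ones(n)
    t = max(1.0, 1.0 / lam)
    mu = 2.0
    iters = 0
    converged = False
    gap = np.inf
    primal = yTy

    while True:
        q = AtA @ c
        AtR = Aty - q                      # A'(y - Ac)
        rTr = max(yTy - 2.0 * (c @ Aty) + c @ q, 0.0)
        rTy = yTy - c @ Aty
        primal, gap = _duality_gap(lam, np.abs(c).sum(), AtR, rTr, rTy)
        if gap <= settings.gap_tol * (1.0 + abs(primal)):
            converged = True
            break
        if iters >= settings.max_iter:
            break

        # barrier weight update (2n log-barrier terms)
        t = max(mu * min(2.0 * n / max(gap, 1e-300), t), t)

        # Newton step on the barrier function phi_t(c, u)
        f1 = u + c
        f2 = u - c
        a = 1.0 / f1**2
        b = 1.0 / f2**2
        gc = -2.0 * t * AtR + (1.0 / f2 - 1.0 / f1)
        gu = t * lam - (1.0 / f1 + 1.0 / f2)
        d1 = a + b
        d2 = a - b
        S = 2.0 * t * AtA + np.diag(d1 - d2 * d2 / d1 + settings.ridge)
        rhs = -(gc - (d2 / d1) * gu)
        try:
            dc = cho_solve(cho_factor(S, lower=True, check_finite=False), rhs, check_finite=False)
        except np.linalg.LinAlgError:
            dc = np.linalg.lstsq(S, rhs, rcond=None)[0]
        du = (-gu - d2 * dc) / d1

        # feasibility-limited backtracking line search on phi_t
        step = 1.0
        df1 = dc + du
        df2 = du - dc
        neg = df1 < 0
        if neg.any():
            step = min(step, 0.99 * np.min(-f1[neg] / df1[neg]))
        neg = df2 < 0
        if neg.any():
            step = min(step, 0.99 * np.min(-f2[neg] / df2[neg]))

        def phi(cc, uu):
            qq = AtA @ cc
            rr = yTy - 2.0 * (cc @ Aty) + cc @ qq
            return t * (rr + lam * uu.sum()) - np.log(uu + cc).sum() - np.log(uu - cc).sum()

        phi0 = phi(c, u)
        slope = gc @ dc + gu @ du
        for _ in range(60):
            cn, un = c + step * dc, u + step * du
            if np.all(un + cn > 0) and np.all(un - cn > 0) and phi(cn, un) <= phi0 + 0.01 * step * slope:
                break
            step *= 0.5
        c, u = c + step * dc, u + step * du
        iters += 1

    return SparseCode(
        coefficients=c,
        lam=lam,
        objective=float(primal),
        duality_gap=float(gap),
        iterations=iters,
        converged=converged,
    )
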