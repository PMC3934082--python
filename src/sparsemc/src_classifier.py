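"""Sparse representation classification (SRC) of patch vectors.

A test vector is sparse-coded over the labelled vocabulary and assigned to
the class whose columns reconstruct it best: for each class ``i`` the
class-restricted code ``delta_i(c)`` keeps only the coefficients of that
class's columns, and the decision is

    f(y) = argmin_i  || y~ - A~ delta_i(c) ||_2

No separate training phase exists; the vocabulary itself is the model.  The
continuous score reported for ROC analysis is the residual difference
``r(-1) - r(+1)`` (larger = more microcalcification-like), the natural
monotone statistic of the argmin rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .evaluation import ScoredPredictions
from .sparse_coding import (
    FeatureTransform,
    SolverSettings,
    SparseCode,
    Vocabulary,
    apply_transform,
    solve_l1ls,
)

__all__ = ["SRCResult", "class_restricted_code", "residual", "classify_src", "src_score_batch"]


@dataclass
class SRCResult:
    """Outcome of classifying one vector: per-class residuals, the argmin
    decision (ties favour +1, the screening-sensitive choice), the continuous
    score ``r(-1) - r(+1)``, and the sparse code that produced them."""

    residuals: dict
    predicted: int
    score: float
    code: SparseCode
    warning: Optional[str] = field(default=None)


def class_restricted_code(coefficients: np.ndarray, labels: np.ndarray, class_i: int) -> np.ndarray:
    """Zero out every coefficient not belonging to ``class_i``.

    The two restrictions partition the code: ``delta_+(c) + delta_-(c) = c``.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    labels = np.asarray(labels)
    if coefficients.shape != labels.shape:
        raise ValueError(
            f"labels shape {labels.shape} does not align with code shape {coefficients.shape}"
        )
    if class_i not in (-1, 1):
        raise ValueError(f"unknown class label {class_i!r}")
    return np.where(labels == class_i, coefficients, 0.0)


def residual(vocab: Vocabulary, y: np.ndarray, restricted_code: np.ndarray) -> float:
    """Euclidean reconstruction residual ``||y - A delta_i(c)||_2``."""
    y = np.asarray(y, dtype=float)
    if vocab.dim != y.shape[0]:
        raise ValueError(f"vocabulary dim {vocab.dim} does not match y length {y.shape[0]}")
    return float(np.linalg.norm(y - vocab.columns @ np.asarray(restricted_code, dtype=float)))


def _normalize(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    if nrm <= np.finfo(float).tiny ** 0.5:
        raise ValueError("cannot normalize an (almost) all-zero test vector")
    return v / nrm


def classify_src(
    vocab: Vocabulary,
    y_raw: np.ndarray,
    transform: Optional[FeatureTransform] = None,
    settings: Optional[SolverSettings] = None,
) -> SRCResult:
    """Run the full SRC chain: transform, normalize, sparse-code, residuals, argmin.

    Solver non-convergence is attached to the result as a warning rather than
    raised — a nearly-converged code still yields usable residuals.
    """
    settings = settings or SolverSettings()
    transform = transform or FeatureTransform.identity()
    y = _normalize(apply_transform(transform, np.asarray(y_raw, dtype=float)))
    code = solve_l1ls(vocab, y, settings)
    warning = None
    if not code.converged:
        warning = f"solver stopped after {code.iterations} iterations with duality gap {code.duality_gap:.3e}"
        warnings.warn(warning, RuntimeWarning, stacklevel=2)
    residuals = {
        cls: residual(vocab, y, class_restricted_code(code.coefficients, vocab.labels, cls))
        for cls in (1, -1)
    }
    predicted = 1 if residuals[1] <= residuals[-1] else -1
    score = residuals[-1] - residuals[1]
    return SRCResult(residuals=residuals, predicted=predicted, score=score, code=code, warning=warning)


def src_score_batch(
    vocab: Vocabulary,
    patches: np.ndarray,
    labels: Optional[np.ndarray] = None,
    transform: Optional[FeatureTransform] = None,
    settings: Optional[SolverSettings] = None,
) -> tuple[ScoredPredictions, list]:
    """Classify each column of ``patches``, preserving order.

    Per-patch failures are recorded (score NaN, result None) and the batch
    continues.  Returns the scored predictions together with the per-patch
    ``SRCResult`` list.
    """
    patches = np.asarray(patches, dtype=float)
    if patches.ndim != 2 or patches.shape[1] == 0:
        raise ValueError("patches must be a nonempty matrix of column vectors")
    scores = np.full(patches.shape[1], np.nan)
    results: list = []
    for j in range(patches.shape[1]):
        try:
            res = classify_src(vocab, patches[:, j], transform, settings)
            scores[j] = res.score
            results.append(res)
        except Exception as exc:  # record, keep going
            warnings.warn(f"patch {j} failed: {exc}", RuntimeWarning, stacklevel=2)
            results.append(None)
    preds = ScoredPredictions(
        scores=scores,
        labels=None if labels is None else np.asarray(labels, dtype=int),
        source="mcs-src",
    )
    return preds, results
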