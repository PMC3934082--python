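"""ROC/Az evaluation, stratified resampling, and the stability experiment.

Az (area under the ROC curve) equals the probability that a randomly chosen
positive outscores a randomly chosen negative; the module computes it both by
a trapezoidal threshold sweep (the working implementation, delegated to
scikit-learn) and by direct Mann-Whitney pair counting (an independent
oracle), which must agree to machine precision.

The stability experiment mirrors the repeated-subsampling protocol of the
detection study: a fixed held-out test pool, and for each repeat and each
training fraction in a grid a fresh stratified subsample of the training pool
is used to fit the method; sensitivity, specificity and Az are aggregated as
mean +/- standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics
from sklearn import model_selection as _skms

from .seeding import child_seed

__all__ = [
    "ScoredPredictions",
    "ROCCurve",
    "EvalReport",
    "roc_curve",
    "auc_pair_oracle",
    "sens_spec",
    "stratified_kfold",
    "train_test_split",
    "stability_experiment",
]


@dataclass
class ScoredPredictions:
    """Continuous classifier scores paired with true binary labels (+1/-1)."""

    scores: np.ndarray
    labels: Optional[np.ndarray] = None
    source: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != self.scores.shape:
                raise ValueError("scores and labels must have equal length")

    def _require_both_classes(self) -> None:
        if self.labels is None:
            raise ValueError("labels are required")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present for ROC analysis")


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    az: float


def roc_curve(preds: ScoredPredictions) -> ROCCurve:
    """Threshold sweep over unique scores (descending), ties grouped; trapezoidal Az."""
    preds._require_both_classes()
    fpr, tpr, thr = _skmetrics.roc_curve(
        preds.labels, preds.scores, pos_label=1, drop_intermediate=False
    )
    az = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr, az=az)


def auc_pair_oracle(preds: ScoredPredictions) -> float:
    """Mann-Whitney pair counting: (concordant + ties/2) / (n_pos * n_neg)."""
    preds._require_both_classes()
    pos = preds.scores[preds.labels == 1]
    neg = preds.scores[preds.labels == -1]
    diff = pos[:, None] - neg[None, :]
    concordant = np.count_nonzero(diff > 0)
    tied = np.count_nonzero(diff == 0)
    return (concordant + 0.5 * tied) / (pos.size * neg.size)


def sens_spec(preds: ScoredPredictions, threshold: float) -> tuple[float, float]:
    """Sensitivity (TP rate) and specificity (TN rate) when score >= threshold -> +1."""
    predicted = np.where(preds.scores >= threshold, 1, -1)
    labels = preds.labels
    pos = labels == 1
    neg = labels == -1
    sens = float(np.mean(predicted[pos] == 1)) if pos.any() else float("nan")
    spec = float(np.mean(predicted[neg] == -1)) if neg.any() else float("nan")
    return sens, spec


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Seeded stratified k-fold partition; returns the k test-index sets."""
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if (counts < k).any():
        raise ValueError(f"every class needs >= {k} members, got {counts.to_dict()}")
    skf = _skms.StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def train_test_split(
    labels: np.ndarray, train_fraction: float = 0.75, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified seeded index split; default 75% train / 25% test."""
    labels = np.asarray(labels)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    idx = np.arange(len(labels))
    train, test = _skms.train_test_split(
        idx, train_size=train_fraction, stratify=labels, random_state=seed, shuffle=True
    )
    if len(train) == 0 or len(test) == 0:
        raise ValueError("split left one side empty")
    return np.sort(train), np.sort(test)


# --------------------------------------------------------------------------
# stability experiment
# --------------------------------------------------------------------------

# A method is a callable (train_columns, train_labels, test_columns) -> scores.
MethodFn = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]

DEFAULT_FRACTIONS: tuple[float, ...] = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))


@dataclass
class EvalReport:
    """Per-repeat/per-fraction metrics with mean +/- std aggregates."""

    rows: pd.DataFrame
    repeats: int
    seeds: dict
    config: dict = field(default_factory=dict)
    n_failures: int = 0

    def summary(self) -> pd.DataFrame:
        return (
            self.rows.groupby("fraction")[["sensitivity", "specificity", "az"]]
            .agg(["mean", "std"])
            .reset_index()
        )

    def overall(self) -> dict:
        out = {}
        for m in ("sensitivity", "specificity", "az"):
            out[m] = {"mean": float(self.rows[m].mean()), "std": float(self.rows[m].std(ddof=1))}
        return out

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "repeats": self.repeats,
            "n_failures": self.n_failures,
            "seeds": self.seeds,
            "config": self.config,
            "overall": self.overall(),
            "rows": self.rows.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def stability_experiment(
    vectors: np.ndarray,
    labels: np.ndarray,
    method: MethodFn,
    repeats: int = 50,
    train_fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    test_fraction: float = 0.25,
    threshold: float = 0.0,
    config: Optional[dict] = None,
) -> EvalReport:
    """Repeated stratified-subsampling evaluation against a fixed test pool.

    ``vectors`` holds one sample per column.  For each repeat ``r`` and each
    fraction ``f`` the method is trained on a stratified fraction ``f`` of the
    training pool (seeded by a per-repeat stream, so extending ``repeats``
    never changes earlier repeats) and scored on the held-out pool.  Failures
    of the method are counted and excluded from the aggregates.
    """
    if repeats < 2:
        raise ValueError("repeats must be >= 2")
    vectors = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels, dtype=int)

    pool_seed = child_seed(seed, "stability-pool")
    train_idx, test_idx = train_test_split(labels, 1.0 - test_fraction, pool_seed)
    X_test, y_test = vectors[:, test_idx], labels[test_idx]
    X_pool, y_pool = vectors[:, train_idx], labels[train_idx]

    records = []
    failures = 0
    for r in range(repeats):
        for f in train_fractions:
            sub_seed = child_seed(seed, f"repeat{r}-frac{f:.6g}")
            if f >= 1.0:
                sub = np.arange(len(y_pool))
            else:
                sub, _ = train_test_split(y_pool, f, sub_seed)
            try:
                scores = np.asarray(method(X_pool[:, sub], y_pool[sub], X_test), dtype=float)
                preds = ScoredPredictions(scores=scores, labels=y_test)
                sens, spec = sens_spec(preds, threshold)
                az = roc_curve(preds).az
            except Exception:
                failures += 1
                continue
            records.append(
                {"repeat": r, "fraction": float(f), "sensitivity": sens, "specificity": spec, "az": az}
            )
    rows = pd.DataFrame.from_records(
        records, columns=["repeat", "fraction", "sensitivity", "specificity", "az"]
    )
    return EvalReport(
        rows=rows,
        repeats=repeats,
        seeds={"global": seed, "pool": pool_seed},
        config=config or {},
        n_failures=failures,
    )
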