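"""Evaluation metrics: ROC-AUC, precision-recall AUC, accuracy, lesion-subset
reports, and fold aggregation.

Conventions, fixed so numbers are comparable across implementations:

* "good" is the positive class (label 1, score = predicted good-probability);
* ROC-AUC is the Mann-Whitney pairwise concordance with ties credited 0.5;
* PR-AUC is average precision (step interpolation, tied scores processed as
  one threshold group) — not trapezoidal PR interpolation, which is biased;
* accuracy thresholds the score at 0.5 (identical to argmax for a two-class
  softmax);
* folds aggregate as mean and sample (n-1) standard deviation, with a single
  fold reporting std 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "MetricsReport",
    "roc_auc",
    "pr_auc",
    "accuracy",
    "compute_report",
    "subset_report",
    "aggregate_folds",
]


@dataclass(frozen=True)
class MetricsReport:
    auc: float
    auc_pr: float
    accuracy: float
    n_voxels: int
    subset_tag: str = "all"

    def __post_init__(self) -> None:
        for name in ("auc", "auc_pr", "accuracy"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_voxels <= 0:
            raise ValueError("n_voxels must be > 0")


def _validate(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same shape")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0=bad, 1=good)")
    return labels.astype(int), scores


def roc_auc(labels, scores) -> float:
    """Mann-Whitney concordance: P(score+ > score-) + 0.5 P(tie)."""
    labels, scores = _validate(labels, scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties with 0.5 credit
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pr_auc(labels, scores) -> float:
    """Average precision with tied scores processed as one threshold group."""
    labels, scores = _validate(labels, scores)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("PR-AUC needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group boundaries: indices where the (descending) score changes
    boundary = np.flatnonzero(np.diff(s) != 0)
    ends = np.append(boundary, s.size - 1)  # inclusive end of each tie group
    tp = np.cumsum(y)[ends]
    n_at = ends + 1
    precision = tp / n_at
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def accuracy(labels, scores, threshold: float = 0.5) -> float:
    """Fraction of voxels whose thresholded score matches the consensus label."""
    labels, scores = _validate(labels, scores)
    pred = (scores >= threshold).astype(int)
    return float(np.mean(pred == labels))


def compute_report(labels, scores, subset_tag: str = "all", threshold: float = 0.5) -> MetricsReport:
    labels_arr, scores_arr = _validate(labels, scores)
    return MetricsReport(
        auc=roc_auc(labels_arr, scores_arr),
        auc_pr=pr_auc(labels_arr, scores_arr),
        accuracy=accuracy(labels_arr, scores_arr, threshold),
        n_voxels=int(labels_arr.size),
        subset_tag=subset_tag,
    )


def subset_report(labels, scores, mask, subset_tag: str = "lesion_only") -> MetricsReport:
    """Metrics restricted to the masked voxels (e.g. T2-lesion members only)."""
    labels, scores = _validate(labels, scores)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != labels.shape:
        raise ValueError("mask must match labels in shape")
    if not mask.any():
        raise ValueError("empty subset: mask selects no voxels")
    return compute_report(labels[mask], scores[mask], subset_tag=subset_tag)


def aggregate_folds(reports: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Per-metric mean and sample std across folds, Table-style ``mean ± std``."""
    if not reports:
        raise ValueError("need at least one fold report")
    out: dict[str, tuple[float, float]] = {}
    for name in ("auc", "auc_pr", "accuracy"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[name] = (float(vals.mean()), std)
    return out
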