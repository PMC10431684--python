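"""Threshold-sweep classification metrics: ROC/AUC and PR/AUPR.

AUC is computed rank-based (Mann-Whitney with ties counted 1/2), which
equals the trapezoidal area under the tie-grouped ROC curve.  AUPR is the
step-wise average precision (trapezoids over-estimate PR area), with tied
scores handled as one group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .network_io import SplitResult

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "evaluation_universe",
    "roc_auc",
    "pr_aupr",
    "evaluate_scores",
    "evaluate_split",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tpr


@dataclass
class EvalResult:
    auc: float
    aupr: float
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    n_pos: int
    n_neg: int


def evaluation_universe(
    split: SplitResult,
    scored: dict[tuple[str, str], float],
    mode: str = "hidden",
) -> tuple[list[float], list[int]]:
    """Labeled scores for the evaluation universe.

    Positives: the hidden positive edges (``mode='hidden'``) or every
    target present edge missing from the input (``mode='all'``); negatives:
    the target's labeled absent edges.  Pairs carrying no target label are
    excluded; a universe pair without a score is an error.
    """
    if mode == "hidden":
        positives = sorted(split.hidden_positive_edges)
    elif mode == "all":
        positives = sorted(
            split.target_network.present_edges - split.input_network.present_edges
        )
    else:
        raise ValueError(f"mode must be 'hidden' or 'all', got {mode!r}")
    negatives = sorted(
        split.target_network.absent_edges - split.input_network.present_edges
    )
    if not positives and not negatives:
        raise ValueError("empty universe: no hidden positives and no labeled absents")
    scores: list[float] = []
    labels: list[int] = []
    missing = []
    for pair, label in [(p, 1) for p in positives] + [(p, 0) for p in negatives]:
        if pair not in scored:
            missing.append(pair)
            continue
        scores.append(scored[pair])
        labels.append(label)
    if missing:
        raise ValueError(f"missing scores for universe pairs: {missing[:10]}")
    return scores, labels


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    return s, y


def roc_auc(scores, labels) -> tuple[float, list[tuple[float, float]]]:
    """Rank-based AUC (ties 1/2) plus the tie-grouped ROC curve.

    The trapezoidal area of the returned curve equals the returned AUC.
    Requires at least one positive and one negative.
    """
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(s)  # average ranks: ties count 1/2 in the Mann-Whitney sum
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(y_sorted[i:j].sum())
        fp += (j - i) - int(y_sorted[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return float(auc), points


def pr_aupr(scores, labels) -> tuple[float, list[tuple[float, float]]]:
    """Average precision with tie grouping, plus (recall, precision) points.

    Each group of equal scores contributes its positive count times the
    precision at the group's end.  Requires at least one positive.
    """
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("AUPR needs at least one positive")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    points: list[tuple[float, float]] = []
    tp = fp = 0
    ap = 0.0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        dtp = int(y_sorted[i:j].sum())
        tp += dtp
        fp += (j - i) - dtp
        precision = tp / (tp + fp)
        recall = tp / n_pos
        points.append((recall, precision))
        ap += dtp * precision
        i = j
    return ap / n_pos, points


def evaluate_scores(scores, labels) -> EvalResult:
    auc, roc_points = roc_auc(scores, labels)
    aupr, pr_points = pr_aupr(scores, labels)
    y = np.asarray(labels, dtype=int)
    return EvalResult(
        auc=auc,
        aupr=aupr,
        roc_points=roc_points,
        pr_points=pr_points,
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
    )


def evaluate_split(
    split: SplitResult,
    scored: dict[tuple[str, str], float],
    mode: str = "hidden",
) -> EvalResult:
    """Convenience: universe construction plus both metrics."""
    scores, labels = evaluation_universe(split, scored, mode)
    return evaluate_scores(scores, labels)
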