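"""Matching picks to ground truth and detection metrics.

Matching is greedy one-to-one by ascending center distance within a match
radius (ground truth in this domain is particle centers). Metrics follow the
standard precision/recall/F1 definitions; the accuracy variant with the full
TP+FP+TN+FN denominator is kept alongside the standard (TP+TN)/total form,
since true negatives are ill-defined for picking and only meaningful for
patch classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import BoundingBox, ParticleCandidate

__all__ = [
    "EvaluationCounts",
    "Metrics",
    "match_picks",
    "metrics",
    "pr_curve",
]


@dataclass(frozen=True)
class EvaluationCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float
    accuracy_paper: float  # TP / (TP + FP + TN + FN)
    accuracy_std: float    # (TP + TN) / (TP + FP + TN + FN)
    zero_division: bool = False


def _centers(items) -> np.ndarray:
    pts = []
    for it in items:
        box = it.box if isinstance(it, ParticleCandidate) else it
        pts.append(box.center if isinstance(box, BoundingBox) else tuple(box))
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def match_picks(picks, truth, match_radius: float) -> EvaluationCounts:
    """Greedy one-to-one matching by ascending center distance.

    A pick matched to a truth center within ``match_radius`` is a TP; each
    remaining pick is an FP and each remaining truth an FN, so
    TP + FP == |picks| and TP + FN == |truth|.
    """
    p = _centers(picks)
    t = _centers(truth)
    if len(p) == 0 or len(t) == 0:
        return EvaluationCounts(tp=0, fp=len(p), fn=len(t))
    d = np.linalg.norm(p[:, None, :] - t[None, :, :], axis=2)
    pairs = [(d[i, j], i, j) for i in range(len(p)) for j in range(len(t))
             if d[i, j] <= match_radius]
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp += 1
    return EvaluationCounts(tp=tp, fp=len(p) - tp, fn=len(t) - tp)


def metrics(counts: EvaluationCounts) -> Metrics:
    """Precision, recall, F1 and both accuracy variants.

    Any zero denominator yields 0 for that metric with the zero_division
    flag set.
    """
    zero = False

    def safe(num: float, den: float) -> float:
        nonlocal zero
        if den == 0:
            zero = True
            return 0.0
        return num / den

    precision = safe(counts.tp, counts.tp + counts.fp)
    recall = safe(counts.tp, counts.tp + counts.fn)
    f1 = safe(2 * precision * recall, precision + recall)
    total = counts.tp + counts.fp + counts.tn + counts.fn
    acc_paper = safe(counts.tp, total)
    acc_std = safe(counts.tp + counts.tn, total)
    return Metrics(precision, recall, f1, acc_paper, acc_std, zero_division=zero)


def pr_curve(scored_picks: list[ParticleCandidate], truth, match_radius: float
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Precision-recall curve over all distinct score thresholds.

    Returns (thresholds desc, precision, recall, area); the area is the
    trapezoid over recall with a (recall=0, first precision) anchor. Raising
    the threshold can only remove picks, so recall is non-increasing along
    the returned ordering.
    """
    if len(truth) == 0:
        raise ValueError("pr_curve needs non-empty ground truth")
    thresholds = sorted({c.score for c in scored_picks}, reverse=True)
    precisions, recalls = [], []
    for thr in thresholds:
        kept = [c for c in scored_picks if c.score >= thr]
        m = metrics(match_picks(kept, truth, match_radius))
        precisions.append(m.precision)
        recalls.append(m.recall)
    if not thresholds:
        return np.array([]), np.array([]), np.array([]), 0.0
    prec = np.asarray(precisions)
    rec = np.asarray(recalls)
    # integrate over recall, anchoring the curve at recall 0
    order = np.argsort(rec, kind="stable")
    r_sorted = np.concatenate([[0.0], rec[order]])
    p_sorted = np.concatenate([[prec[order][0]], prec[order]])
    area = float(np.trapezoid(p_sorted, r_sorted))
    return np.asarray(thresholds), prec, rec, area
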