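"""Per-cell IOU matching and AP50:95-style precision.

Ground-truth and predicted instance masks are compared cell by cell with
the intersection-over-union (Jaccard) overlap.  For every threshold T in
{0.50, 0.55, ..., 0.95} a one-to-one assignment is made greedily on
descending IOU; a ground-truth cell matched with IOU strictly greater than
T is a true positive, an unmatched ground-truth cell a false negative and
an unmatched predicted cell a false positive.  The per-image precision is

    precision = (1/|{T_k}|) * sum_k TP_k / (TP_k + FN_k + FP_k)

and each ground-truth cell is additionally assigned its matched IOU (0.0
when unmatched at the assignment threshold) whose per-image mean is the
"average IOU".  Dataset aggregation reports mean +/- population standard
deviation of the per-image average IOUs and the mean precision.

For thresholds >= 0.5 greedy one-to-one assignment is provably identical
to a maximum bipartite matching: two disjoint ground-truth cells cannot
both overlap one predicted cell with IOU > 0.5.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EvalConfig", "MatchResult", "iou_matrix", "match_cells",
           "precision", "evaluate_dataset"]


def _default_thresholds():
    return tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass
class EvalConfig:
    thresholds: tuple = field(default_factory=_default_thresholds)
    iou_assign_threshold: float = 0.50

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if t.size == 0 or (np.diff(t) <= 0).any() or t.min() <= 0 or t.max() >= 1:
            raise ValueError("thresholds must be strictly increasing in (0, 1)")
        if not 0 <= self.iou_assign_threshold < 1:
            raise ValueError("iou_assign_threshold must lie in [0, 1)")


@dataclass
class MatchResult:
    per_gt_iou: list  # one value per ground-truth cell, 0.0 for FN
    per_threshold_counts: list  # [(T_k, TP_k, FN_k, FP_k)]


def _relabel(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    out = np.zeros_like(mask, dtype=np.int32)
    for new, old in enumerate(labels, start=1):
        out[mask == old] = new
    return out


def iou_matrix(gt: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Pairwise IOU between ground-truth and predicted instances.

    Entry (i, j) is |g_i ∩ p_j| / |g_i ∪ p_j| for 1-based labels i, j.
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"iou_matrix: shape mismatch {gt.shape} vs {pred.shape}")
    gt = _relabel(gt)
    pred = _relabel(pred)
    ng, npred = int(gt.max()), int(pred.max())
    if ng == 0 or npred == 0:
        return np.zeros((ng, npred))
    inter = np.histogram2d(gt.ravel(), pred.ravel(),
                           bins=(np.arange(ng + 2) - 0.5,
                                 np.arange(npred + 2) - 0.5))[0][1:, 1:]
    area_g = np.bincount(gt.ravel(), minlength=ng + 1)[1:]
    area_p = np.bincount(pred.ravel(), minlength=npred + 1)[1:]
    union = area_g[:, None] + area_p[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def _greedy_assignment(iou: np.ndarray, threshold: float):
    """One-to-one assignment on descending IOU, strictly above threshold.

    Ties break on lower predicted label id, then lower ground-truth id.
    Returns {gt_index: (pred_index, iou)}.
    """
    ng, npred = iou.shape
    cands = [(iou[i, j], i, j) for i in range(ng) for j in range(npred)
             if iou[i, j] > threshold]
    cands.sort(key=lambda t: (-t[0], t[2], t[1]))
    used_g, used_p, assign = set(), set(), {}
    for v, i, j in cands:
        if i in used_g or j in used_p:
            continue
        used_g.add(i)
        used_p.add(j)
        assign[i] = (j, v)
    return assign


def match_cells(gt: np.ndarray, pred: np.ndarray,
                config: EvalConfig = EvalConfig()) -> MatchResult:
    """Per-threshold TP/FN/FP counts and per-ground-truth-cell IOUs."""
    iou = iou_matrix(gt, pred)
    ng, npred = iou.shape
    counts = []
    for t in config.thresholds:
        assign = _greedy_assignment(iou, t)
        tp = len(assign)
        counts.append((float(t), tp, ng - tp, npred - tp))
    base = _greedy_assignment(iou, config.iou_assign_threshold)
    per_gt = [base[i][1] if i in base else 0.0 for i in range(ng)]
    return MatchResult(per_gt_iou=per_gt, per_threshold_counts=counts)


def precision(match: MatchResult) -> float:
    """Eq.-style AP50:95 precision; an empty/empty image scores 1.0."""
    vals = []
    for _, tp, fn, fp in match.per_threshold_counts:
        denom = tp + fn + fp
        vals.append(1.0 if denom == 0 else tp / denom)
    return float(np.mean(vals))


def evaluate_dataset(pairs, config: EvalConfig = EvalConfig()) -> dict:
    """Aggregate per-image average IOU (mean +/- population std) and precision.

    ``pairs`` is a list of (gt_instances, pred_instances) arrays.  Images
    without ground-truth cells contribute average IOU 1.0 when the
    prediction is also empty and 0.0 otherwise.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_dataset needs at least one image pair")
    per_image = []
    for gt, pred in pairs:
        m = match_cells(gt, pred, config)
        if m.per_gt_iou:
            avg_iou = float(np.mean(m.per_gt_iou))
        else:
            avg_iou = 1.0 if m.per_threshold_counts[0][3] == 0 else 0.0
        per_image.append({"avg_iou": avg_iou, "precision": precision(m),
                          "n_gt": len(m.per_gt_iou)})
    ious = np.array([r["avg_iou"] for r in per_image])
    precs = np.array([r["precision"] for r in per_image])
    return {
        "per_image": per_image,
        "mean_iou": float(ious.mean()),
        "std_iou": float(ious.std()),  # population standard deviation
        "mean_precision": float(precs.mean()),
        "mean_precision_pct": float(100.0 * precs.mean()),
        "n_images": len(per_image),
    }
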