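"""Detection, tracking, and counting evaluation statistics.

Detection quality is scored by precision, recall, and average precision
(all-point interpolated area under the precision-recall curve, matches at
IoU >= 0.5).  Tracking quality follows the CLEAR-MOT convention:

    MOTA = 1 - sum_t (m_t + fp_t + mme_t) / sum_t g_t

where per frame t, ``m_t`` counts missed ground-truth boxes, ``fp_t``
spurious result boxes, ``mme_t`` identity switches, and ``g_t`` the
ground-truth box count.  Counting quality is the mean per-video relative
error MAE = (1/m) * sum_i |y_i - gt_i| / gt_i plus an ordinary
least-squares fit of predicted against true counts with its R².

All values are fractions here; percent formatting belongs to the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import linregress

from .errors import ValidationError
from .mot import Detection, GroundTruthEntry
from .tracker import associate, iou, iou_matrix

__all__ = [
    "DetectionTally",
    "TrackingTally",
    "CountEvaluation",
    "precision_recall",
    "label_detections",
    "average_precision",
    "mean_ap",
    "mota",
    "match_and_tally",
    "mae",
    "linear_fit_r2",
]


@dataclass
class DetectionTally:
    """True/false positive and false negative counts at one threshold."""

    tp: int
    fp: int
    fn: int
    nc: int = 1

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValidationError("tally counts must be non-negative")


@dataclass
class TrackingTally:
    """Per-frame CLEAR-MOT error counts."""

    misses: list[int] = field(default_factory=list)  # m_t
    false_positives: list[int] = field(default_factory=list)  # fp_t
    mismatches: list[int] = field(default_factory=list)  # mme_t
    gt_counts: list[int] = field(default_factory=list)  # g_t

    def append(self, m: int, fp: int, mme: int, g: int) -> None:
        if min(m, fp, mme, g) < 0 or m > g:
            raise ValidationError(f"invalid frame tally m={m}, fp={fp}, mme={mme}, g={g}")
        self.misses.append(m)
        self.false_positives.append(fp)
        self.mismatches.append(mme)
        self.gt_counts.append(g)

    @property
    def ids(self) -> int:
        return int(sum(self.mismatches))


@dataclass
class CountEvaluation:
    """Predicted vs true per-video fruit counts."""

    predicted: Sequence[float]
    truth: Sequence[float]

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.truth = np.asarray(self.truth, dtype=float)
        if len(self.predicted) != len(self.truth) or len(self.truth) < 1:
            raise ValidationError("need matched, non-empty predicted/truth count vectors")
        if np.any(self.truth <= 0):
            raise ValidationError("true counts must be positive")


def precision_recall(tally: DetectionTally) -> tuple[Optional[float], Optional[float]]:
    """Exact P = TP/(TP+FP) and R = TP/(TP+FN); ``None`` where 0/0."""
    p = tally.tp / (tally.tp + tally.fp) if tally.tp + tally.fp > 0 else None
    r = tally.tp / (tally.tp + tally.fn) if tally.tp + tally.fn > 0 else None
    return p, r


def label_detections(
    detections: Sequence[Detection],
    ground_truth: Sequence[GroundTruthEntry],
    iou_thresh: float = 0.5,
) -> tuple[list[bool], int]:
    """Greedy TP/FP labeling of score-ranked detections against ground truth.

    Detections are visited in descending score order; each matches the
    best-IoU unclaimed ground-truth box on its frame (IoU >= threshold), and
    every ground-truth box can be claimed once.  Returns the ranked label
    list and the ground-truth count.
    """
    gt_by_frame: dict[int, list[GroundTruthEntry]] = {}
    for g in ground_truth:
        gt_by_frame.setdefault(g.frame, []).append(g)
    claimed: set[int] = set()
    order = sorted(range(len(detections)), key=lambda i: -detections[i].score)
    labels = [False] * len(detections)
    for i in order:
        det = detections[i]
        best, best_iou = None, iou_thresh
        for g in gt_by_frame.get(det.frame, []):
            if id(g) in claimed:
                continue
            v = iou(det.bbox, g.bbox)
            if v >= best_iou:
                best, best_iou = g, v
        if best is not None:
            claimed.add(id(best))
            labels[i] = True
    return [labels[i] for i in order], len(ground_truth)


def average_precision(ranked_labels: Sequence[bool], n_gt: int) -> float:
    """All-point interpolated area under the precision-recall curve.

    ``ranked_labels`` are TP/FP flags in descending score order.  The
    precision envelope (running maximum from the right) is integrated as a
    step function over recall.
    """
    if n_gt < 1:
        raise ValidationError("need at least one ground-truth object")
    labels = np.asarray(ranked_labels, dtype=bool)
    if labels.size == 0 or not labels.any():
        return 0.0
    tp = np.cumsum(labels)
    fp = np.cumsum(~labels)
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # envelope: precision at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


def mean_ap(per_class_ap: Sequence[float]) -> float:
    """Arithmetic mean of per-class average precisions."""
    aps = np.asarray(per_class_ap, dtype=float)
    if aps.size < 1:
        raise ValidationError("need at least one class AP")
    return float(aps.mean())


def mota(tally: TrackingTally) -> float:
    """Multiple-object tracking accuracy; may be negative."""
    g = sum(tally.gt_counts)
    if g <= 0:
        raise ValidationError("MOTA undefined: no ground-truth objects")
    errors = sum(tally.misses) + sum(tally.false_positives) + sum(tally.mismatches)
    return 1.0 - errors / g


def match_and_tally(
    gt: Sequence[GroundTruthEntry],
    results: Sequence[GroundTruthEntry],
    iou_thresh: float = 0.5,
) -> tuple[TrackingTally, int]:
    """CLEAR-MOT per-frame matching of tracker output against ground truth.

    Per frame, previous-frame (gt id, result id) pairs are kept when their
    boxes still overlap at the threshold; the rest are matched by
    IoU-gated optimal assignment.  A mismatch (``mme_t``) is counted when a
    ground-truth identity's matched result id differs from the result id it
    had at its previous *matched* frame.  Unmatched ground-truth boxes are
    misses; unmatched result boxes are false positives.  Returns the tally
    and total identity switches.
    """
    gt_frames: dict[int, list[GroundTruthEntry]] = {}
    res_frames: dict[int, list[GroundTruthEntry]] = {}
    for g in gt:
        gt_frames.setdefault(g.frame, []).append(g)
    for r in results:
        res_frames.setdefault(r.frame, []).append(r)
    if not gt_frames:
        raise ValidationError("ground truth is empty")
    frames = sorted(set(gt_frames) | set(res_frames))

    tally = TrackingTally()
    prev_pair: dict[int, int] = {}  # gt id -> result id matched last frame
    last_matched: dict[int, int] = {}  # gt id -> result id at last matched frame
    for f in frames:
        gts = gt_frames.get(f, [])
        ress = res_frames.get(f, [])
        matches: dict[int, int] = {}
        used_res: set[int] = set()
        # persistence: keep previous pairs still above the gate
        res_by_id = {r.track_id: r for r in ress}
        for g in gts:
            rid = prev_pair.get(g.track_id)
            if rid is not None and rid in res_by_id and rid not in used_res:
                if iou(g.bbox, res_by_id[rid].bbox) >= iou_thresh:
                    matches[g.track_id] = rid
                    used_res.add(rid)
        # optimal assignment for the rest
        free_g = [g for g in gts if g.track_id not in matches]
        free_r = [r for r in ress if r.track_id not in used_res]
        if free_g and free_r:
            cost = 1.0 - iou_matrix([g.bbox for g in free_g], [r.bbox for r in free_r])
            cost[cost > 1.0 - iou_thresh] = 1e6
            pairs, _, _ = associate(cost, 1.0 - iou_thresh)
            for i, j in pairs:
                matches[free_g[i].track_id] = free_r[j].track_id
                used_res.add(free_r[j].track_id)
        mme = 0
        for gid, rid in matches.items():
            if gid in last_matched and last_matched[gid] != rid:
                mme += 1
            last_matched[gid] = rid
        m = len(gts) - len(matches)
        fp = len(ress) - len(matches)
        tally.append(m=m, fp=fp, mme=mme, g=len(gts))
        prev_pair = dict(matches)
    return tally, tally.ids


def mae(ev: CountEvaluation) -> float:
    """Mean per-video relative counting error."""
    return float(np.mean(np.abs(ev.predicted - ev.truth) / ev.truth))


def linear_fit_r2(pairs: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """OLS fit of predicted count on true count: (slope, intercept, R²)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValidationError("need at least two (truth, predicted) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.allclose(x, x[0]):
        raise ValidationError("true counts are all identical; fit undefined")
    fit = linregress(x, y)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0.0:
        r2 = 0.0
    else:
        resid = y - (fit.slope * x + fit.intercept)
        r2 = 1.0 - np.sum(resid**2) / ss_tot
    return float(fit.slope), float(fit.intercept), float(r2)
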