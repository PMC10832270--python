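"""Detection evaluation: IoU, class-wise NMS, greedy matching, P/R/F1, AP, mAP.

A detection is a true positive iff it shares the ground-truth class and
overlaps an unmatched ground-truth box with IoU above the threshold (0.5 by
default), matched greedily one-to-one in descending score order.  From the
ordered TP/FP flags:

    P = TP/(TP+FP),  R = TP/(TP+FN),  F1 = 2PR/(P+R),  AP = integral P(R) dR

AP uses the all-point interpolated precision envelope by default (the exact
area under the interpolated curve); the coarser 11-point variant is
available for comparison.  mAP averages AP over classes; mAP@[0.5:0.95]
additionally averages over the ten IoU thresholds 0.50, 0.55, ..., 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .voc import BoundingBox

__all__ = [
    "Detection", "MatchResult", "MetricsReport", "iou", "nms",
    "match_detections", "precision_recall_f1", "f1_score", "average_precision",
    "mean_ap", "evaluate_detections", "COCO_THRESHOLDS",
]

COCO_THRESHOLDS = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))


@dataclass(frozen=True)
class Detection:
    image_id: str
    label: str
    score: float
    box: BoundingBox

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0) or not np.isfinite(self.score):
            raise ValueError(f"score must be a finite value in [0,1], got {self.score}")


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    flags: list            # per-detection True (TP) / False (FP), score-descending
    scores: list

    @property
    def n_gt(self) -> int:
        return self.tp + self.fn


@dataclass
class MetricsReport:
    per_class_ap: dict
    precision: float
    recall: float
    f1: float
    map50: float
    map50_95: float
    per_class_counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "per_class_ap": dict(self.per_class_ap),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mAP@0.5": self.map50,
            "mAP@[0.5:0.95]": self.map50_95,
        }


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 iff identical."""
    ix = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    iy = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def nms(dets, iou_threshold: float = 0.3):
    """Class-wise greedy non-maximum suppression.

    Keep the highest-scoring detection, drop same-class detections whose IoU
    with a kept box exceeds the threshold; repeat.  Detections of different
    classes never suppress each other.
    """
    kept = []
    by_class: dict = {}
    for d in dets:
        by_class.setdefault(d.label, []).append(d)
    for label in by_class:
        pool = sorted(by_class[label], key=lambda d: -d.score)
        while pool:
            best = pool.pop(0)
            kept.append(best)
            pool = [d for d in pool if iou(best.box, d.box) <= iou_threshold]
    return sorted(kept, key=lambda d: -d.score)


def match_detections(dets, gts, iou_threshold: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching in descending score order.

    ``gts`` are (image_id, BoundingBox) pairs (or bare boxes for a single
    image).  A detection only ever matches ground truth of its own image and
    class; ties on IoU break toward the higher-IoU ground-truth box.
    """
    norm_gts = [g if isinstance(g, tuple) else ("", g) for g in gts]
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    matched = [False] * len(norm_gts)
    flags, scores = [], []
    tp = 0
    for i in order:
        d = dets[i]
        best_j, best_iou = -1, iou_threshold
        for j, (img, g) in enumerate(norm_gts):
            if matched[j] or g.label != d.label or img != d.image_id:
                continue
            v = iou(d.box, g)
            if v > best_iou:
                best_j, best_iou = j, v
        hit = best_j >= 0
        if hit:
            matched[best_j] = True
            tp += 1
        flags.append(hit)
        scores.append(d.score)
    fp = len(dets) - tp
    fn = len(norm_gts) - tp
    return MatchResult(tp, fp, fn, flags, scores)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(mr: MatchResult):
    """P, R and F1 from match counts; 0/0 reported as 0 by convention."""
    tp, fp, fn = mr.tp, mr.fp, mr.fn
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r, f1_score(p, r)


def average_precision(flags, n_gt: int, method: str = "all_point") -> float:
    """Area under the interpolated precision/recall curve.

    ``flags`` are score-ordered TP/FP indicators.  ``all_point`` computes the
    exact area under the monotone precision envelope; ``eleven_point``
    averages the envelope at recalls 0, 0.1, ..., 1.
    """
    if n_gt == 0:
        return 0.0
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # monotone non-increasing precision envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if method == "eleven_point":
        pts = []
        for r in np.linspace(0, 1, 11):
            mask = recall >= r - 1e-12
            pts.append(env[mask].max() if mask.any() else 0.0)
        return float(np.mean(pts))
    if method != "all_point":
        raise ValueError(f"unknown AP method {method!r}")
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        if r > r_prev:
            ap += (r - r_prev) * p
            r_prev = r
    return float(ap)


def mean_ap(per_class_ap: dict) -> float:
    """Mean over classes of the per-class AP."""
    if not per_class_ap:
        return 0.0
    return float(np.mean(list(per_class_ap.values())))


def evaluate_detections(dets, gts, class_names, iou_threshold: float = 0.5,
                        conf_threshold: float = 0.5,
                        map_thresholds=COCO_THRESHOLDS,
                        ap_method: str = "all_point") -> MetricsReport:
    """Full metrics over a detection set.

    ``gts`` is a list of (image_id, BoundingBox) pairs.  Per-class AP at
    ``iou_threshold`` uses every detection (ranked by score); the headline
    precision/recall/F1 are computed at the confidence threshold; the
    mAP@[0.5:0.95]-style average spans ``map_thresholds``.
    """
    dets = sorted(dets, key=lambda d: -d.score)
    per_class_ap, counts = {}, {}

    def class_subset(label):
        return ([d for d in dets if d.label == label],
                [g for g in gts if g[1].label == label])

    for label in class_names:
        cd, cg = class_subset(label)
        mr = match_detections(cd, cg, iou_threshold)
        per_class_ap[label] = average_precision(mr.flags, len(cg), ap_method)
        counts[label] = {"tp": mr.tp, "fp": mr.fp, "fn": mr.fn, "n_gt": len(cg)}

    conf_dets = [d for d in dets if d.score >= conf_threshold]
    mr_all = match_detections(conf_dets, gts, iou_threshold)
    p, r, f1 = precision_recall_f1(mr_all)

    # classes absent from the ground truth have undefined AP and are left out
    # of the means (their per-class entry stays 0-flagged)
    present = [label for label in class_names if counts[label]["n_gt"] > 0]
    ap_grid = []
    for t in map_thresholds:
        aps = []
        for label in present:
            cd, cg = class_subset(label)
            mr = match_detections(cd, cg, t)
            aps.append(average_precision(mr.flags, len(cg), ap_method))
        ap_grid.append(float(np.mean(aps)) if aps else 0.0)

    return MetricsReport(per_class_ap, p, r, f1,
                         map50=mean_ap({k: per_class_ap[k] for k in present}),
                         map50_95=float(np.mean(ap_grid)) if ap_grid else 0.0,
                         per_class_counts=counts)
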