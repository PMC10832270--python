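"""Detection metrics against independent brute-force references."""

import itertools

import numpy as np
import pytest

from kcc.evaluation import (Detection, MatchResult, average_precision,
                            evaluate_detections, f1_score, iou, match_detections,
                            mean_ap, nms, precision_recall_f1)
from kcc.voc import BoundingBox


def B(x0, y0, x1, y1, label="Ulmus pumila"):
    return BoundingBox(x0, y0, x1, y1, label)


def D(box, score, label=None, image_id="img"):
    return Detection(image_id, label or box.label, score, box)


def test_iou_examples():
    assert iou(B(0, 0, 10, 10), B(0, 0, 10, 10)) == 1.0
    assert iou(B(0, 0, 10, 10), B(20, 20, 30, 30)) == 0.0
    assert iou(B(0, 0, 10, 10), B(5, 0, 15, 10)) == pytest.approx(1 / 3)


def test_nms_keeps_best_and_separates_classes():
    a = B(0, 0, 10, 10)
    kept = nms([D(a, 0.9), D(a, 0.8)], 0.3)
    assert len(kept) == 1 and kept[0].score == 0.9
    kept = nms([D(a, 0.9, "Ulmus pumila"), D(a, 0.8, "dead trees")], 0.3)
    assert len(kept) == 2


def brute_force_nms(dets, thr):
    """Independent O(n^2) suppression: repeatedly take the global best per
    class and delete everything it covers."""
    kept = []
    pool = list(dets)
    while pool:
        best = max(pool, key=lambda d: d.score)
        kept.append(best)
        pool = [d for d in pool
                if not (d.label == best.label and iou(d.box, best.box) > thr)]
    return kept


def test_nms_agrees_with_brute_force_on_random_sets():
    rng = np.random.default_rng(0)
    labels = ["a", "b", "c"]
    for _ in range(200):
        dets = []
        for _ in range(int(rng.integers(0, 21))):
            x0, y0 = rng.uniform(0, 80, size=2)
            w, h = rng.uniform(5, 40, size=2)
            dets.append(Detection("img", labels[int(rng.integers(3))],
                                  float(rng.random()),
                                  BoundingBox(x0, y0, x0 + w, y0 + h, "x")))
        got = {(d.score, d.label) for d in nms(dets, 0.3)}
        ref = {(d.score, d.label) for d in brute_force_nms(dets, 0.3)}
        assert got == ref


def test_matching_perfect_and_empty():
    gts = [("img", B(0, 0, 10, 10)), ("img", B(20, 20, 40, 40))]
    dets = [D(g[1], 0.9) for g in gts]
    mr = match_detections(dets, gts)
    assert (mr.tp, mr.fp, mr.fn) == (2, 0, 0)
    mr = match_detections([], gts)
    assert (mr.tp, mr.fp, mr.fn) == (0, 0, 2)


def test_matching_is_one_to_one():
    gt = [("img", B(0, 0, 10, 10))]
    dets = [D(B(0, 0, 10, 10), 0.9), D(B(1, 0, 11, 10), 0.8)]
    mr = match_detections(dets, gt)
    assert (mr.tp, mr.fp, mr.fn) == (1, 1, 0)
    assert mr.flags == [True, False]


def test_matching_respects_class_and_image():
    gt = [("img1", B(0, 0, 10, 10))]
    wrong_class = [D(B(0, 0, 10, 10), 0.9, "dead trees")]
    assert match_detections(wrong_class, gt).tp == 0
    wrong_image = [D(B(0, 0, 10, 10), 0.9, image_id="img2")]
    assert match_detections(wrong_image, gt).tp == 0


def test_f1_reproduces_published_rows():
    """Printed precision/recall pairs of the ablation table reproduce the
    printed F1 for the self-consistent rows."""
    assert round(f1_score(0.9793, 0.9812), 2) == 0.98
    assert round(f1_score(0.9450, 0.9274), 3) == 0.936
    assert round(f1_score(0.9586, 0.9447), 3) == 0.952


def test_prf_degenerate_zero_convention():
    mr = MatchResult(0, 0, 0, [], [])
    assert precision_recall_f1(mr) == (0.0, 0.0, 0.0)


def test_average_precision_hand_examples():
    assert average_precision([True], 1) == 1.0
    assert average_precision([False, True], 1) == pytest.approx(0.5)
    # trailing false positives after full recall leave AP unchanged
    assert average_precision([True, False, False], 1) == 1.0
    assert average_precision([], 5) == 0.0
    assert average_precision([True], 0) == 0.0


def test_eleven_point_vs_all_point():
    flags = [True, False, True, False, True]
    ap_all = average_precision(flags, 3)
    ap_11 = average_precision(flags, 3, method="eleven_point")
    assert 0 < ap_all <= 1 and 0 < ap_11 <= 1


def test_mean_ap_trivial_cases():
    assert mean_ap({"a": 1.0, "b": 1.0}) == 1.0
    assert mean_ap({"a": 1.0, "b": 0.0}) == 0.5
    assert mean_ap({}) == 0.0


# --- brute-force evaluator reference --------------------------------------

def reference_metrics(dets, gts, class_names, thr):
    """Independent per-class AP: exhaustive greedy matching re-implemented
    from scratch plus a fine Riemann sum over the interpolated PR curve."""
    out = {}
    for label in class_names:
        cd = sorted([d for d in dets if d.label == label], key=lambda d: -d.score)
        cg = [g for g in gts if g[1].label == label]
        if not cg:
            out[label] = None
            continue
        used = set()
        flags = []
        for d in cd:
            cand = [(iou(d.box, g[1]), j) for j, g in enumerate(cg)
                    if j not in used and g[0] == d.image_id]
            cand = [c for c in cand if c[0] > thr]
            if cand:
                best = max(cand)
                used.add(best[1])
                flags.append(1)
            else:
                flags.append(0)
        if not flags:
            out[label] = 0.0
            continue
        tp = np.cumsum(flags)
        rec = tp / len(cg)
        prec = tp / np.arange(1, len(flags) + 1)
        env = np.maximum.accumulate(prec[::-1])[::-1]
        rs = np.linspace(0, 1, 10001)
        ps = np.zeros_like(rs)
        for i, r in enumerate(rs):
            mask = rec >= r - 1e-12
            ps[i] = env[mask].max() if mask.any() else 0.0
        # exact area: integrate the step function between achieved recalls
        ap = 0.0
        r_prev = 0.0
        for r, p in zip(rec, env):
            if r > r_prev:
                ap += (r - r_prev) * p
                r_prev = r
        out[label] = ap
    return out


def random_scene(rng, n_classes=3):
    labels = [f"c{k}" for k in range(n_classes)]
    gts, dets = [], []
    for img in ("i0", "i1"):
        for _ in range(int(rng.integers(1, 5))):
            x0, y0 = rng.uniform(0, 60, size=2)
            w, h = rng.uniform(8, 40, size=2)
            lab = labels[int(rng.integers(n_classes))]
            gts.append((img, BoundingBox(x0, y0, x0 + w, y0 + h, lab)))
        for _ in range(int(rng.integers(0, 8))):
            x0, y0 = rng.uniform(0, 60, size=2)
            w, h = rng.uniform(8, 40, size=2)
            lab = labels[int(rng.integers(n_classes))]
            dets.append(Detection(img, lab, float(rng.random()),
                                  BoundingBox(x0, y0, x0 + w, y0 + h, lab)))
    return dets, gts, labels


def test_evaluator_matches_brute_force_reference():
    """Per-class AP agrees with the independent reference to 1e-6 on 100
    random small scenes."""
    rng = np.random.default_rng(123)
    for _ in range(100):
        dets, gts, labels = random_scene(rng)
        rep = evaluate_detections(dets, gts, labels, iou_threshold=0.5)
        ref = reference_metrics(dets, gts, labels, 0.5)
        for label in labels:
            if ref[label] is None:
                continue
            assert rep.per_class_ap[label] == pytest.approx(ref[label], abs=1e-6)


def test_perfect_detections_give_unit_ap():
    rng = np.random.default_rng(9)
    dets, gts = [], []
    for i in range(10):
        x0, y0 = rng.uniform(0, 50, size=2)
        b = BoundingBox(x0, y0, x0 + 20, y0 + 15, "c0")
        gts.append((f"i{i}", b))
        dets.append(Detection(f"i{i}", "c0", 0.9, b))
    rep = evaluate_detections(dets, gts, ["c0"])
    assert rep.map50 == 1.0 and rep.f1 == 1.0


def test_strict_map_never_exceeds_map50():
    rng = np.random.default_rng(31)
    for _ in range(10):
        dets, gts, labels = random_scene(rng)
        rep = evaluate_detections(dets, gts, labels)
        assert rep.map50_95 <= rep.map50 + 1e-12
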