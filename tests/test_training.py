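"""Target assignment, composite loss, schedule and the training loop."""

import math

import numpy as np
import pytest

from kcc import nd
from kcc.anchors import AnchorSet, STRIDES
from kcc.augment import LabeledImage
from kcc.network import ModelConfig, build_model
from kcc.training import (TrainConfig, assign_targets, cosine_lr, detection_loss,
                          evaluate_model, train)
from kcc.voc import BoundingBox, DatasetIndex, ImageAnnotation

ANCHORS = AnchorSet(((16, 16), (24, 20), (28, 28),
                     (40, 40), (52, 44), (60, 60),
                     (90, 80), (110, 110), (140, 130)))
NAMES = ("Ulmus pumila", "Populus bolleana", "Haloxylon ammodendron",
         "Elaeagnus angustifolia", "dead trees")
CLASS_IDS = {n: i for i, n in enumerate(NAMES)}


def make_li(boxes, size=160, seed=0):
    rng = np.random.default_rng(seed)
    return LabeledImage(rng.random((size, size, 3)),
                        ImageAnnotation("t.jpg", size, size, boxes))


def test_exact_anchor_match_is_positive_at_center_cell():
    # a box exactly equal to anchor (16,16), centered in cell (5,5) of stride 8
    box = BoundingBox(36, 36, 52, 52, NAMES[0])
    asg = assign_targets([make_li([box])], ANCHORS, 160, neighbor_cells=False)
    p = asg.positives[0]
    assert 0 in p["a"]
    k = list(p["a"]).index(0)
    assert (p["i"][k], p["j"][k]) == (5, 5)
    assert asg.obj_targets[0][0, 0, 5, 5] == 1.0


def test_empty_annotation_all_negative():
    asg = assign_targets([make_li([])], ANCHORS, 160)
    assert asg.n_positive == 0
    assert all(t.sum() == 0 for t in asg.obj_targets)


def test_every_positive_passes_iou_or_is_argmax_fallback():
    rng = np.random.default_rng(4)
    boxes = []
    for _ in range(12):
        w, h = rng.uniform(6, 120, size=2)
        x0 = rng.uniform(0, 160 - w)
        y0 = rng.uniform(0, 160 - h)
        boxes.append(BoundingBox(x0, y0, x0 + w, y0 + h, NAMES[int(rng.integers(5))]))
    li = make_li(boxes)
    asg = assign_targets([li], ANCHORS, 160, match_iou=0.5)
    flat_anchors = np.array([a for s in STRIDES for a in ANCHORS.scale_groups[s]])

    def dim_iou(wh, a):
        inter = min(wh[0], a[0]) * min(wh[1], a[1])
        return inter / (wh[0] * wh[1] + a[0] * a[1] - inter)

    for si, stride in enumerate(STRIDES):
        p = asg.positives[si]
        for k in range(len(p["b"])):
            gt = p["gt"][k]
            wh = (gt[2] - gt[0], gt[3] - gt[1])
            a = ANCHORS.scale_groups[stride][p["a"][k]]
            if dim_iou(wh, a) > 0.5:
                continue
            best = max(dim_iou(wh, fa) for fa in flat_anchors)
            assert dim_iou(wh, a) == pytest.approx(best)


def test_detection_loss_zero_positives():
    model = build_model(ModelConfig(width_scale=0.125, input_size=64, anchors=ANCHORS))
    li = make_li([], size=64)
    preds = model(np.stack([li.pixels.transpose(2, 0, 1)]))
    asg = assign_targets([li], ANCHORS, 64)
    total, box_t, obj_t, cls_t = detection_loss(preds, asg, ANCHORS, 5, CLASS_IDS)
    assert box_t.item() == 0.0 and cls_t.item() == 0.0
    assert obj_t.item() > 0.0
    assert total.item() > 0.0 and math.isfinite(total.item())


def test_detection_loss_rejects_nan_predictions():
    model = build_model(ModelConfig(width_scale=0.125, input_size=64, anchors=ANCHORS))
    li = make_li([BoundingBox(10, 10, 30, 30, NAMES[0])], size=64)
    preds = model(np.stack([li.pixels.transpose(2, 0, 1)]))
    preds[0].data[0, 0, 0, 0, 0] = np.nan
    asg = assign_targets([li], ANCHORS, 64)
    with pytest.raises(FloatingPointError):
        detection_loss(preds, asg, ANCHORS, 5, CLASS_IDS)


def test_cosine_schedule_closed_form():
    assert cosine_lr(0, 100, 0.01) == pytest.approx(0.01)
    assert cosine_lr(100, 100, 0.01) == pytest.approx(0.0)
    assert cosine_lr(50, 100, 0.01) == pytest.approx(0.005)
    assert cosine_lr(50, 100, 0.01, lr_min=0.002) == pytest.approx(0.006)
    with pytest.raises(ValueError):
        cosine_lr(101, 100, 0.01)


def test_loss_decreases_when_overfitting_one_batch():
    """First 20 optimization steps on a fixed batch reduce the loss."""
    nd.set_default_dtype(np.float32)
    model = build_model(ModelConfig(width_scale=0.125, input_size=64,
                                    anchors=ANCHORS, init_seed=1))
    rng = np.random.default_rng(0)
    boxes = [BoundingBox(8, 8, 30, 28, NAMES[0]), BoundingBox(34, 30, 58, 56, NAMES[3])]
    li = LabeledImage(rng.random((64, 64, 3)).astype(np.float32),
                      ImageAnnotation("t.jpg", 64, 64, boxes))
    x = np.stack([li.pixels.transpose(2, 0, 1)])
    asg = assign_targets([li], ANCHORS, 64)
    opt = nd.Adam(model.parameters(), lr=1e-3)
    losses = []
    for _ in range(20):
        preds = model(x)
        total, *_ = detection_loss(preds, asg, ANCHORS, 5, CLASS_IDS,
                                   box_weight=1.0, cls_weight=0.5)
        opt.zero_grad()
        total.backward()
        opt.step()
        losses.append(total.item())
    assert losses[-1] < 0.75 * losses[0]
    assert np.mean(losses[-5:]) < np.mean(losses[:5])
    drops = sum(b <= a + 1e-6 for a, b in zip(losses, losses[1:]))
    assert drops >= 12      # decreasing trend; BN coupling allows upticks
    assert all(math.isfinite(v) for v in losses)


def _tiny_index(n=4, size=64, seed=0):
    rng = np.random.default_rng(seed)
    from kcc.scenes import default_scene_spec, generate_scene
    from PIL import Image
    import tempfile, pathlib
    d = pathlib.Path(tempfile.mkdtemp())
    spec = default_scene_spec(size, size, size_scale=0.3, crowns_per_image=(1, 3))
    items = []
    for i in range(n):
        arr, ann = generate_scene(spec, seed + i)
        p = d / f"s{i}.jpg"
        Image.fromarray(arr).save(p, quality=95)
        ann.image_path = p
        items.append(ann)
    return DatasetIndex(items, spec.catalog)


def test_train_log_shape_and_determinism():
    """One log row per epoch; a re-run with the same seed reproduces the
    epoch-1 loss to six decimals."""
    nd.set_default_dtype(np.float32)
    index = _tiny_index()

    def run():
        model = build_model(ModelConfig(width_scale=0.125, input_size=64,
                                        anchors=ANCHORS, init_seed=3))
        cfg = TrainConfig(epochs=2, batch_size=2, lr0=1e-3, seed=5, val_every=10,
                          warmup_epochs=0)
        _, log = train(model, index, None, cfg)
        return log

    log1, log2 = run(), run()
    assert len(log1) == 2
    assert [r["epoch"] for r in log1] == [0, 1]
    assert log1[0]["loss"] == pytest.approx(log2[0]["loss"], abs=1e-6)
    assert set(log1[0]) == {"epoch", "loss", "box", "obj", "cls", "lr",
                            "val_p", "val_r", "val_map50"}


def test_train_writes_checkpoints_and_csv(tmp_path):
    nd.set_default_dtype(np.float32)
    index = _tiny_index(n=2)
    model = build_model(ModelConfig(width_scale=0.125, input_size=64,
                                    anchors=ANCHORS, init_seed=3))
    cfg = TrainConfig(epochs=1, batch_size=2, lr0=1e-3, seed=5, val_every=1,
                      warmup_epochs=0)
    train(model, index, index, cfg, out_dir=tmp_path)
    assert (tmp_path / "metrics.csv").exists()
    assert (tmp_path / "last.ckpt.npz").exists()
    header = (tmp_path / "metrics.csv").read_text().splitlines()[0]
    assert header == "epoch,loss,box,obj,cls,lr,val_p,val_r,val_map50"


def test_train_rejects_empty_dataset():
    model = build_model(ModelConfig(width_scale=0.125, input_size=64, anchors=ANCHORS))
    with pytest.raises(ValueError):
        train(model, DatasetIndex([]), None, TrainConfig(epochs=1))
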