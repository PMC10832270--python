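"""Training: anchor-to-target assignment, composite detection loss, cosine
learning-rate schedule and the Adam training loop.

The loss is the standard single-stage composite — the source method does not
publish its loss, so the conventional form is used and documented as such:

* box term: mean (1 - CIoU) between decoded predictions and ground truth at
  positive anchors;
* objectness term: binary cross-entropy over every cell of every grid
  (positives carry their MixUp provenance weight);
* classification term: softmax cross-entropy on positives by default (the
  species labels are mutually exclusive); per-class binary cross-entropy is
  selectable.

A ground-truth box becomes positive at the cell owning its center, for every
anchor of that scale whose corner-aligned dimension IoU with the box exceeds
``match_iou``; if no anchor passes anywhere, the single best-matching anchor
is used as a fallback so every box is learned from.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import nd
from .nd import Tensor, functional as F
from .anchors import STRIDES, AnchorSet
from .augment import AugmentPolicy, load_labeled_image, online_pipeline, resize
from .evaluation import MetricsReport, evaluate_detections, nms
from .network import DetectionModel, decode, save_checkpoint
from .voc import DatasetIndex

__all__ = ["TrainConfig", "TargetAssignment", "assign_targets", "detection_loss",
           "cosine_lr", "train", "evaluate_model", "recalibrate_batchnorm"]

LOG_HEADER = ("epoch", "loss", "box", "obj", "cls", "lr", "val_p", "val_r", "val_map50")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 300
    lr0: float = 0.01
    lr_min: float = 0.0
    weight_decay: float = 0.0001
    beta1: float = 0.937           # the recipe's "learning rate momentum"
    beta2: float = 0.999
    batch_size: int = 4
    nms_threshold: float = 0.3
    conf_threshold: float = 0.5
    match_iou: float = 0.5
    seed: int = 0
    box_weight: float = 0.05
    obj_weight: float = 1.0
    obj_pos_weight: float = 1.0    # extra weight on positive cells in the obj term
    cls_weight: float | None = None   # default 0.5 * num_classes / 80
    cls_mode: str = "softmax"      # "softmax" (exclusive species) or "bce"
    augment: AugmentPolicy | None = None
    val_every: int = 1
    grad_clip: float = 10.0        # global gradient-norm cap; 0 disables
    warmup_epochs: int = 3         # linear ramp 0 -> lr0 before cosine decay
    box_logit_l2: float = 0.01     # keeps raw box logits out of sigmoid saturation

    def __post_init__(self):
        if min(self.epochs, self.lr0, self.batch_size) <= 0:
            raise ValueError("epochs, lr0 and batch_size must be positive")
        for t in (self.nms_threshold, self.conf_threshold, self.match_iou):
            if not 0.0 < t < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class TargetAssignment:
    """Positive-anchor bookkeeping for one batch."""

    obj_targets: list        # per scale: (N, 3, H, W) float
    obj_weights: list        # per scale: same shape; MixUp weight at positives
    positives: list          # per scale: dict of index arrays + gt boxes/classes/weights
    n_positive: int


def _dim_iou(wh: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Corner-aligned IoU between box dims (M,2) and anchors (K,2) -> (M,K)."""
    inter = (np.minimum(wh[:, None, 0], anchors[None, :, 0])
             * np.minimum(wh[:, None, 1], anchors[None, :, 1]))
    union = wh[:, 0:1] * wh[:, 1:2] + (anchors[:, 0] * anchors[:, 1])[None, :] - inter
    return inter / union


def assign_targets(batch, anchors: AnchorSet, input_size: int,
                   match_iou: float = 0.5, neighbor_cells: bool = True) -> TargetAssignment:
    """Build positive/negative targets for a batch of LabeledImages.

    With ``neighbor_cells`` (the center-prior convention) each matched
    anchor is also made positive at the two cells adjacent to the box
    center — the decode offset range (-0.5, 1.5) covers them — which
    densifies the objectness signal.
    """
    groups = anchors.scale_groups
    n = len(batch)
    shapes = [(n, 3, input_size // s, input_size // s) for s in STRIDES]
    obj_t = [np.zeros(sh) for sh in shapes]
    obj_w = [np.ones(sh) for sh in shapes]
    pos = [{"b": [], "a": [], "i": [], "j": [], "gt": [], "cls": [], "w": []}
           for _ in STRIDES]
    anchor_mat = np.array([groups[s] for s in STRIDES], dtype=float)  # (3 scales, 3, 2)
    n_pos = 0
    # two claim rounds: every box's center cell first, then neighbor cells
    # into still-free slots — a crown's own center cell is never stolen by
    # an adjacent crown's neighbor expansion
    claims = {0: [], 1: []}
    for b, li in enumerate(batch):
        weights = li.box_weights
        for box, wgt in zip(li.ann.boxes, weights):
            bx = box.clipped(input_size, input_size)
            cx, cy = (bx.xmin + bx.xmax) / 2, (bx.ymin + bx.ymax) / 2
            wh = np.array([[bx.width, bx.height]])
            ious = _dim_iou(wh, anchor_mat.reshape(-1, 2))[0]        # (9,)
            chosen = np.nonzero(ious > match_iou)[0]
            if chosen.size == 0:
                chosen = np.array([int(np.argmax(ious))])            # best-anchor fallback
            for flat in chosen:
                si, ai = divmod(int(flat), 3)
                stride = STRIDES[si]
                gh, gw = shapes[si][2], shapes[si][3]
                j = min(int(cx // stride), gw - 1)
                i = min(int(cy // stride), gh - 1)
                claims[0].append((si, b, ai, i, j, bx, box.label, wgt))
                if neighbor_cells:
                    jn = j + (1 if cx / stride - j > 0.5 else -1)
                    in_ = i + (1 if cy / stride - i > 0.5 else -1)
                    if 0 <= jn < gw:
                        claims[1].append((si, b, ai, i, jn, bx, box.label, wgt))
                    if 0 <= in_ < gh:
                        claims[1].append((si, b, ai, in_, j, bx, box.label, wgt))
    for round_ in (0, 1):
        for si, b, ai, ci, cj, bx, label, wgt in claims[round_]:
            if obj_t[si][b, ai, ci, cj] > 0:
                continue                                              # cell-anchor taken
            obj_t[si][b, ai, ci, cj] = 1.0
            obj_w[si][b, ai, ci, cj] = wgt
            p = pos[si]
            p["b"].append(b); p["a"].append(ai); p["i"].append(ci); p["j"].append(cj)
            p["gt"].append([bx.xmin, bx.ymin, bx.xmax, bx.ymax])
            p["cls"].append(label)
            p["w"].append(wgt)
            n_pos += 1
    for p in pos:
        for k in ("b", "a", "i", "j"):
            p[k] = np.asarray(p[k], dtype=int)
        p["gt"] = np.asarray(p["gt"], dtype=float).reshape(-1, 4)
        p["w"] = np.asarray(p["w"], dtype=float)
    return TargetAssignment(obj_t, obj_w, pos, n_pos)


def _ciou(px0, py0, px1, py1, gt: np.ndarray) -> Tensor:
    """Complete IoU between predicted corner tensors and constant GT boxes."""
    gx0, gy0, gx1, gy1 = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]
    iw = px1.minimum(gx1) - px0.maximum(gx0)
    ih = py1.minimum(gy1) - py0.maximum(gy0)
    inter = iw.clamp(lo=0.0) * ih.clamp(lo=0.0)
    area_p = (px1 - px0) * (py1 - py0)
    area_g = (gx1 - gx0) * (gy1 - gy0)
    iou = inter / (area_p + area_g - inter + 1e-9)
    # center distance over enclosing-box diagonal
    d2 = (((px0 + px1) - (gx0 + gx1)) * 0.5) ** 2 + (((py0 + py1) - (gy0 + gy1)) * 0.5) ** 2
    cw = px1.maximum(gx1) - px0.minimum(gx0)
    chh = py1.maximum(gy1) - py0.minimum(gy0)
    c2 = cw ** 2 + chh ** 2 + 1e-9
    # aspect-ratio consistency
    v = (4.0 / math.pi ** 2) * (
        (Tensor(np.arctan((gx1 - gx0) / (gy1 - gy0)))
         - ((px1 - px0) / (py1 - py0 + 1e-9)).arctan()) ** 2)
    alpha = v.numpy() / (1.0 - iou.numpy() + v.numpy() + 1e-9)   # treated as constant
    return iou - d2 / c2 - Tensor(alpha) * v


def detection_loss(preds, assignment: TargetAssignment, anchors: AnchorSet,
                   num_classes: int, class_ids: dict,
                   box_weight=0.05, obj_weight=1.0, cls_weight=None,
                   obj_pos_weight=1.0, box_logit_l2=0.01, cls_mode="softmax"):
    """Composite loss; returns (total, box_term, obj_term, cls_term) Tensors."""
    if cls_weight is None:
        cls_weight = 0.5 * num_classes / 80.0
    groups = anchors.scale_groups
    box_terms, cls_terms, obj_total = [], [], None
    n_pos_total = assignment.n_positive
    for si, (grid, stride) in enumerate(zip(preds, STRIDES)):
        if not np.all(np.isfinite(grid.numpy())):
            raise FloatingPointError(f"non-finite predictions at stride {stride}")
        obj_logits = grid[..., 4]
        obj_w = assignment.obj_weights[si]
        if obj_pos_weight != 1.0:
            obj_w = obj_w * np.where(assignment.obj_targets[si] > 0, obj_pos_weight, 1.0)
        term = F.bce_with_logits(obj_logits, assignment.obj_targets[si],
                                 weights=obj_w, reduction="mean")
        obj_total = term if obj_total is None else obj_total + term
        p = assignment.positives[si]
        if len(p["b"]) == 0:
            continue
        sel = grid[p["b"], p["a"], p["i"], p["j"]]          # (P, 5+nc)
        anc = np.asarray(groups[stride], dtype=float)[p["a"]]
        cx = (sel[:, 0].sigmoid() * 2.0 - 0.5 + p["j"]) * stride
        cy = (sel[:, 1].sigmoid() * 2.0 - 0.5 + p["i"]) * stride
        bw = (sel[:, 2].sigmoid() * 2.0) ** 2 * anc[:, 0]
        bh = (sel[:, 3].sigmoid() * 2.0) ** 2 * anc[:, 1]
        ciou = _ciou(cx - bw * 0.5, cy - bh * 0.5, cx + bw * 0.5, cy + bh * 0.5, p["gt"])
        box_loss = (1.0 - ciou) * p["w"]
        if box_logit_l2:
            # CIoU's gradient vanishes deep in sigmoid saturation; a weak
            # quadratic pull on the raw logits keeps them recoverable
            box_loss = box_loss + box_logit_l2 * (sel[:, 0:4] ** 2).sum(axis=1)
        box_terms.append(box_loss.sum())
        onehot = np.zeros((len(p["b"]), num_classes))
        onehot[np.arange(len(p["b"])), [class_ids[c] for c in p["cls"]]] = 1.0
        logits = sel[:, 5:]
        if cls_mode == "softmax":
            # species labels are mutually exclusive: cross-entropy over a
            # softmax keeps class scores competitive, suppressing duplicate
            # detections of a second species on the same crown
            shifted = logits - logits.numpy().max(axis=1, keepdims=True)
            lse = shifted.exp().sum(axis=1).log()
            z_true = (shifted * onehot).sum(axis=1)
            cls_terms.append(((lse - z_true) * p["w"]).sum())
        elif cls_mode == "bce":
            cls_terms.append(F.bce_with_logits(logits, onehot,
                                               weights=p["w"][:, None], reduction="sum")
                             * (1.0 / num_classes))
        else:
            raise ValueError(f"unknown cls_mode {cls_mode!r}")
    zero = Tensor(0.0)
    box_term = (sum(box_terms, zero) * (1.0 / max(1, n_pos_total))) if box_terms else zero
    cls_term = (sum(cls_terms, zero) * (1.0 / max(1, n_pos_total))) if cls_terms else zero
    total = box_weight * box_term + obj_weight * obj_total + cls_weight * cls_term
    return total, box_term, obj_total, cls_term


def cosine_lr(step: int, total_steps: int, lr0: float, lr_min: float = 0.0) -> float:
    """Cosine annealing: lr0 at step 0, lr_min at the final step."""
    if not 0 <= step <= total_steps:
        raise ValueError("step must lie in [0, total_steps]")
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * step / total_steps))


def recalibrate_batchnorm(model: DetectionModel, images, batch_size: int = 2):
    """Replace BatchNorm running statistics with exact train-set averages.

    With tiny batches the exponentially averaged statistics lag the weights;
    one pass over the training images in train mode, averaging batch moments
    uniformly, removes the train/eval normalization gap.
    """
    from .nd.modules import BatchNorm2d

    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    sums = [(np.zeros_like(b.running_mean), np.zeros_like(b.running_var)) for b in bns]
    saved = [(b.momentum,) for b in bns]
    for b in bns:
        b.momentum = 1.0          # running stats become the current batch stats
    model.train()
    n_batches = 0
    with nd.no_grad():
        for start in range(0, len(images), batch_size):
            batch = images[start:start + batch_size]
            x = np.stack([li.pixels.transpose(2, 0, 1) for li in batch])
            model(x)
            for (ms, vs), b in zip(sums, bns):
                ms += b.running_mean
                vs += b.running_var
            n_batches += 1
    for (ms, vs), b, (mom,) in zip(sums, bns, saved):
        b.running_mean = ms / n_batches
        b.running_var = vs / n_batches
        b.momentum = mom
    return model


def _prepare(index: DatasetIndex, size: int):
    out = []
    for ann in index.items:
        li = load_labeled_image(ann)
        if (li.ann.width, li.ann.height) != (size, size):
            li = resize(li, size)
        out.append(li)
    return out


def evaluate_model(model: DetectionModel, index: DatasetIndex,
                   conf_threshold: float = 0.5, nms_threshold: float = 0.3,
                   iou_threshold: float = 0.5, ap_conf: float = 0.01) -> MetricsReport:
    """Run inference over a dataset and score it against its own labels."""
    size = model.cfg.input_size
    model.eval()
    dets, gts = [], []
    for ann in index.items:
        li = load_labeled_image(ann)
        sx, sy = li.ann.width / size, li.ann.height / size
        li_r = resize(li, size) if (li.ann.width, li.ann.height) != (size, size) else li
        with nd.no_grad():
            grids = model(li_r.pixels.transpose(2, 0, 1)[None])
        img_id = str(ann.image_path)
        raw = decode(grids, model.cfg.effective_anchors, conf_threshold=ap_conf,
                     class_names=index.catalog.names, image_ids=[img_id])
        for d in nms(raw, nms_threshold):
            b = d.box
            x0, y0 = max(0.0, b.xmin * sx), max(0.0, b.ymin * sy)
            x1 = min(float(li.ann.width), b.xmax * sx)
            y1 = min(float(li.ann.height), b.ymax * sy)
            if x1 - x0 >= 1 and y1 - y0 >= 1:
                dets.append(replace(d, box=replace(b, xmin=x0, ymin=y0, xmax=x1, ymax=y1)))
        gts.extend((img_id, b) for b in ann.boxes)
    return evaluate_detections(dets, gts, index.catalog.names,
                               iou_threshold=iou_threshold, conf_threshold=conf_threshold)


def train(model: DetectionModel, train_index: DatasetIndex,
          val_index: DatasetIndex | None, cfg: TrainConfig,
          out_dir=None):
    """Train the detector; returns (model, per-epoch log rows).

    Writes ``metrics.csv`` plus best-mAP and last checkpoints when
    ``out_dir`` is given.  Fully deterministic for a fixed config seed.
    """
    if len(train_index) == 0:
        raise ValueError("training set is empty")
    size = model.cfg.input_size
    images = _prepare(train_index, size)
    rng = np.random.default_rng(cfg.seed)
    opt = nd.Adam(model.parameters(), lr=cfg.lr0, betas=(cfg.beta1, cfg.beta2),
                  weight_decay=cfg.weight_decay)
    class_ids = {name: i for i, name in enumerate(train_index.catalog.names)}
    anchors = model.cfg.effective_anchors
    log = []
    best_map, best_path = -1.0, None
    out_dir = Path(out_dir) if out_dir is not None else None
    val_p = val_r = val_map = float("nan")
    warmup = min(cfg.warmup_epochs, max(0, cfg.epochs - 1))
    for epoch in range(cfg.epochs):
        if epoch < warmup:
            opt.lr = cfg.lr0 * (epoch + 1) / (warmup + 1)
        else:
            opt.lr = cosine_lr(epoch - warmup, cfg.epochs - warmup, cfg.lr0, cfg.lr_min)
        model.train()
        if cfg.augment is not None:
            pool = list(online_pipeline(images, replace(cfg.augment,
                                                        seed=cfg.augment.seed + epoch),
                                        out_size=size))
        else:
            pool = [images[i] for i in rng.permutation(len(images))]
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, len(pool), cfg.batch_size):
            batch = pool[start:start + cfg.batch_size]
            x = np.stack([li.pixels.transpose(2, 0, 1) for li in batch])
            preds = model(x)
            assignment = assign_targets(batch, anchors, size, cfg.match_iou)
            total, box_t, obj_t, cls_t = detection_loss(
                preds, assignment, anchors, model.cfg.num_classes, class_ids,
                cfg.box_weight, cfg.obj_weight, cfg.cls_weight, cfg.obj_pos_weight,
                cfg.box_logit_l2, cfg.cls_mode)
            opt.zero_grad()
            total.backward()
            if cfg.grad_clip:
                norm = math.sqrt(sum(float((p.grad ** 2).sum())
                                     for p in opt.params if p.grad is not None))
                if norm > cfg.grad_clip:
                    scale = cfg.grad_clip / norm
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            sums += [total.item(), box_t.item(), obj_t.item(), cls_t.item()]
            n_batches += 1
        means = sums / max(1, n_batches)
        if val_index is not None and (epoch + 1) % cfg.val_every == 0:
            rep = evaluate_model(model, val_index, cfg.conf_threshold, cfg.nms_threshold)
            val_p, val_r, val_map = rep.precision, rep.recall, rep.map50
            if out_dir is not None and rep.map50 > best_map:
                best_map = rep.map50
                best_path = save_checkpoint(model, out_dir / "best.ckpt.npz")
        log.append(dict(zip(LOG_HEADER,
                            (epoch, *means, opt.lr, val_p, val_r, val_map))))
    recalibrate_batchnorm(model, images, cfg.batch_size)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, out_dir / "last.ckpt.npz")
        with open(out_dir / "metrics.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=LOG_HEADER)
            writer.writeheader()
            writer.writerows(log)
    return model, log
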