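"""The detector architecture: CoordConv-enhanced ELAN backbone, SPPCSPC,
PANet neck with five CBAM insertion sites, RepConv fusion and three
anchor-based detection heads at strides 8/16/32.

Structure (input -> three detection grids):

* **Backbone** — a CBS stem (conv + batch-norm + SiLU) followed by four
  ELAN stages separated by MP downsampling blocks, emitting feature maps
  feat1/feat2/feat3 at strides 8/16/32.  Inside each ELAN the two 1x1 entry
  convolutions are CoordConv layers (two normalized coordinate ramp channels
  appended before the convolution) when the ``coordconv`` flag is on.
* **Neck** — CBAM gates feat1/feat2/feat3; SPPCSPC pools the deepest map at
  kernel sizes 5/9/13; a PANet top-down path (with CBAM after each of the
  two upsampling layers) and bottom-up path fuse scales.
* **Head** — RepConv (3x3 conv+BN, 1x1 conv+BN and identity-BN branches,
  summed) feeds a 1x1 convolution per scale producing
  (tx, ty, tw, th, objectness, class logits) for 3 anchors per cell.

Every enhancement — clustered anchors, CoordConv, CBAM — toggles
independently from :class:`ModelConfig`, so all eight on/off combinations
(baseline included) build the corresponding ablation variants structurally.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nd
from .nd import Tensor, functional as F
from .anchors import PAPER_ANCHORS, STRIDES, AnchorSet
from .attention import CBAM
from .evaluation import Detection
from .voc import BoundingBox

__all__ = ["ModelConfig", "CoordConv", "CBS", "ELAN", "MPDown", "SPPCSPC", "RepConv",
           "DetectionModel", "build_model", "decode", "save_checkpoint", "load_checkpoint",
           "DEFAULT_ANCHORS"]

#: Hand-set priors of the upstream single-stage baseline (used when the
#: clustered-anchor flag is off, i.e. the un-refined ablation rows).
DEFAULT_ANCHORS = ((12, 16), (19, 36), (40, 28), (36, 75), (76, 55),
                   (72, 146), (142, 110), (192, 243), (459, 401))


@dataclass(frozen=True)
class ModelConfig:
    num_classes: int = 5
    anchors: AnchorSet = field(default_factory=lambda: AnchorSet(PAPER_ANCHORS))
    input_size: int = 640
    width_scale: float = 1.0
    use_cbam: bool = True
    use_coordconv: bool = True
    use_kmeans_anchors: bool = True
    cbam_reduction: int = 16
    cbam_merge: str = "sum"
    init_seed: int = 0

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if len(self.anchors) != 9:
            raise ValueError("model expects 9 anchors (3 per scale)")

    @property
    def effective_anchors(self) -> AnchorSet:
        return self.anchors if self.use_kmeans_anchors else AnchorSet(DEFAULT_ANCHORS)

    def hash(self) -> str:
        payload = json.dumps({
            "num_classes": self.num_classes, "anchors": self.effective_anchors.anchors,
            "input_size": self.input_size, "width_scale": self.width_scale,
            "cbam": self.use_cbam, "coordconv": self.use_coordconv,
            "kmeans": self.use_kmeans_anchors, "reduction": self.cbam_reduction,
            "merge": self.cbam_merge}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def coordinate_channels(h: int, w: int) -> np.ndarray:
    """x/y ramp channels in [-1, 1]; a degenerate axis maps to 0 (midpoint)."""
    xs = np.linspace(-1.0, 1.0, w) if w > 1 else np.zeros(1)
    ys = np.linspace(-1.0, 1.0, h) if h > 1 else np.zeros(1)
    return np.stack(np.meshgrid(xs, ys, indexing="xy"), axis=0)  # (2, H, W): x then y


class CoordConv(nd.Module):
    """Convolution over the input augmented with coordinate ramp channels."""

    def __init__(self, in_ch, out_ch, kernel=1, stride=1, bias=True, rng=None):
        super().__init__()
        self.conv = nd.Conv2d(in_ch + 2, out_ch, kernel, stride=stride, bias=bias, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, _, h, w = x.shape
        coords = np.broadcast_to(coordinate_channels(h, w), (n, 2, h, w))
        return self.conv(nd.concat([x, Tensor(coords)], axis=1))


class CBS(nd.Module):
    """Conv -> BatchNorm -> SiLU, same-padding."""

    def __init__(self, in_ch, out_ch, kernel=1, stride=1, rng=None):
        super().__init__()
        self.conv = nd.Conv2d(in_ch, out_ch, kernel, stride=stride, bias=False, rng=rng)
        self.bn = nd.BatchNorm2d(out_ch)

    def forward(self, x):
        return self.bn(self.conv(x)).silu()


class _CoordCBS(nd.Module):
    """CBS whose convolution sees two extra coordinate channels."""

    def __init__(self, in_ch, out_ch, kernel=1, stride=1, rng=None):
        super().__init__()
        self.conv = nd.Conv2d(in_ch + 2, out_ch, kernel, stride=stride, bias=False, rng=rng)
        self.bn = nd.BatchNorm2d(out_ch)

    def forward(self, x):
        n, _, h, w = x.shape
        coords = np.broadcast_to(coordinate_channels(h, w), (n, 2, h, w))
        return self.bn(self.conv(nd.concat([x, Tensor(coords)], axis=1))).silu()


class ELAN(nd.Module):
    """Efficient layer aggregation block (two branches, four taps, 1x1 fuse).

    Branch 1: 1x1 channel transform.  Branch 2: 1x1 transform then four 3x3
    CBS blocks.  The four taps — branch 1, branch 2 entry, after two convs,
    after four convs — are concatenated and fused by a 1x1 CBS.  With the
    ``coordconv`` flag the two 1x1 entry convolutions become CoordConv.
    """

    def __init__(self, in_ch, hidden, out_ch, coordconv=False, rng=None):
        super().__init__()
        entry = _CoordCBS if coordconv else CBS
        self.branch1 = entry(in_ch, hidden, 1, rng=rng)
        self.branch2_in = entry(in_ch, hidden, 1, rng=rng)
        self.convs = [CBS(hidden, hidden, 3, rng=rng) for _ in range(4)]
        self.fuse = CBS(4 * hidden, out_ch, 1, rng=rng)
        self.hidden = hidden

    def forward(self, x):
        t1 = self.branch1(x)
        t2 = self.branch2_in(x)
        c1 = self.convs[1](self.convs[0](t2))
        c2 = self.convs[3](self.convs[2](c1))
        return self.fuse(nd.concat([t1, t2, c1, c2], axis=1))


class MPDown(nd.Module):
    """Two-branch downsampling: maxpool + 1x1 conv vs 1x1 conv + strided 3x3."""

    def __init__(self, in_ch, out_ch, rng=None):
        super().__init__()
        half = out_ch // 2
        self.p_conv = CBS(in_ch, half, 1, rng=rng)
        self.c_conv1 = CBS(in_ch, half, 1, rng=rng)
        self.c_conv2 = CBS(half, half, 3, stride=2, rng=rng)

    def forward(self, x):
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError(f"MP downsampling needs even spatial dims, got {x.shape[2:]}")
        b1 = self.p_conv(F.max_pool2d(x, 2, 2))
        b2 = self.c_conv2(self.c_conv1(x))
        return nd.concat([b1, b2], axis=1)


class SPPCSPC(nd.Module):
    """CSP-wrapped spatial pyramid pooling at kernel sizes 5/9/13."""

    def __init__(self, in_ch, out_ch, pool_sizes=(5, 9, 13), rng=None):
        super().__init__()
        h = max(1, out_ch // 2)
        self.pool_sizes = tuple(pool_sizes)
        self.cv1 = CBS(in_ch, h, 1, rng=rng)
        self.cv2 = CBS(h, h, 3, rng=rng)
        self.cv3 = CBS(h, h, 1, rng=rng)
        self.cv4 = CBS(h * (1 + len(self.pool_sizes)), h, 1, rng=rng)
        self.cv5 = CBS(h, h, 3, rng=rng)
        self.shortcut = CBS(in_ch, h, 1, rng=rng)
        self.out = CBS(2 * h, out_ch, 1, rng=rng)

    def forward(self, x):
        y = self.cv3(self.cv2(self.cv1(x)))
        pools = [y] + [F.max_pool2d(y, k, stride=1, padding=k // 2) for k in self.pool_sizes]
        y = self.cv5(self.cv4(nd.concat(pools, axis=1)))
        return self.out(nd.concat([y, self.shortcut(x)], axis=1))


class RepConv(nd.Module):
    """Sum of 3x3 conv+BN, 1x1 conv+BN and identity+BN branches."""

    def __init__(self, in_ch, out_ch, rng=None):
        super().__init__()
        self.conv3 = nd.Conv2d(in_ch, out_ch, 3, bias=False, rng=rng)
        self.bn3 = nd.BatchNorm2d(out_ch)
        self.conv1 = nd.Conv2d(in_ch, out_ch, 1, bias=False, rng=rng)
        self.bn1 = nd.BatchNorm2d(out_ch)
        self.identity = in_ch == out_ch
        self.bn_id = nd.BatchNorm2d(out_ch) if self.identity else None

    def forward(self, x):
        y = self.bn3(self.conv3(x)) + self.bn1(self.conv1(x))
        if self.identity:
            y = y + self.bn_id(x)
        return y


class _MaybeCBAM(nd.Module):
    def __init__(self, channels, cfg: ModelConfig, rng=None):
        super().__init__()
        self.block = (CBAM(channels, cfg.cbam_reduction, cfg.cbam_merge, rng=rng)
                      if cfg.use_cbam else nd.Identity())

    def forward(self, x):
        return self.block(x)


class DetectionModel(nd.Module):
    """Backbone + neck + three detection heads; forward returns raw grids.

    Each grid has shape (N, 3, H/stride, W/stride, 5 + num_classes) holding
    (tx, ty, tw, th, objectness, class logits).
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.init_seed)

        def ch(c):  # scaled channel width
            return max(2, int(round(c * cfg.width_scale)))

        cc = cfg.use_coordconv
        self.stem = nd.Sequential(
            CBS(3, ch(32), 3, rng=rng), CBS(ch(32), ch(64), 3, 2, rng=rng),
            CBS(ch(64), ch(64), 3, rng=rng), CBS(ch(64), ch(128), 3, 2, rng=rng))
        self.elan1 = ELAN(ch(128), ch(64), ch(256), cc, rng)
        self.mp1 = MPDown(ch(256), ch(256), rng)
        self.elan2 = ELAN(ch(256), ch(128), ch(512), cc, rng)     # -> feat1, stride 8
        self.mp2 = MPDown(ch(512), ch(512), rng)
        self.elan3 = ELAN(ch(512), ch(256), ch(1024), cc, rng)    # -> feat2, stride 16
        self.mp3 = MPDown(ch(1024), ch(1024), rng)
        self.elan4 = ELAN(ch(1024), ch(256), ch(1024), cc, rng)   # -> feat3, stride 32

        # CBAM sites: the three backbone taps + the two upsample outputs
        self.cbam_feat1 = _MaybeCBAM(ch(512), cfg, rng)
        self.cbam_feat2 = _MaybeCBAM(ch(1024), cfg, rng)
        self.cbam_feat3 = _MaybeCBAM(ch(1024), cfg, rng)
        self.cbam_up4 = _MaybeCBAM(ch(256), cfg, rng)
        self.cbam_up3 = _MaybeCBAM(ch(128), cfg, rng)

        self.sppcspc = SPPCSPC(ch(1024), ch(512), rng=rng)
        self.reduce_p5 = CBS(ch(512), ch(256), 1, rng=rng)
        self.lat_f2 = CBS(ch(1024), ch(256), 1, rng=rng)
        self.elan_n4 = ELAN(ch(512), ch(128), ch(256), False, rng)
        self.reduce_p4 = CBS(ch(256), ch(128), 1, rng=rng)
        self.lat_f1 = CBS(ch(512), ch(128), 1, rng=rng)
        self.elan_n3 = ELAN(ch(256), ch(64), ch(128), False, rng)
        self.down_p3 = MPDown(ch(128), ch(256), rng)
        self.elan_n4b = ELAN(ch(512), ch(128), ch(256), False, rng)
        self.down_p4 = MPDown(ch(256), ch(512), rng)
        self.elan_n5 = ELAN(ch(1024), ch(256), ch(512), False, rng)

        self.rep3 = RepConv(ch(128), ch(256), rng)
        self.rep4 = RepConv(ch(256), ch(512), rng)
        self.rep5 = RepConv(ch(512), ch(1024), rng)
        no = 3 * (5 + cfg.num_classes)
        self.head3 = nd.Conv2d(ch(256), no, 1, rng=rng)
        self.head4 = nd.Conv2d(ch(512), no, 1, rng=rng)
        self.head5 = nd.Conv2d(ch(1024), no, 1, rng=rng)
        # start objectness strongly negative so early grids are near-empty
        for head in (self.head3, self.head4, self.head5):
            b = head.bias.data.reshape(3, 5 + cfg.num_classes)
            b[:, 4] = -4.0
            head.bias.data = b.reshape(-1)

    # ---------------------------------------------------------------- forward
    def forward(self, x) -> list:
        x = nd.as_tensor(x)
        t = self.stem(x)
        t = self.elan1(t)
        feat1 = self.elan2(self.mp1(t))
        feat2 = self.elan3(self.mp2(feat1))
        feat3 = self.elan4(self.mp3(feat2))

        f1 = self.cbam_feat1(feat1)
        f2 = self.cbam_feat2(feat2)
        f3 = self.cbam_feat3(feat3)

        p5 = self.sppcspc(f3)
        up4 = self.cbam_up4(F.upsample_nearest(self.reduce_p5(p5)))
        n4 = self.elan_n4(nd.concat([self.lat_f2(f2), up4], axis=1))
        up3 = self.cbam_up3(F.upsample_nearest(self.reduce_p4(n4)))
        n3 = self.elan_n3(nd.concat([self.lat_f1(f1), up3], axis=1))

        p3 = n3
        p4 = self.elan_n4b(nd.concat([self.down_p3(p3), n4], axis=1))
        p5b = self.elan_n5(nd.concat([self.down_p4(p4), p5], axis=1))

        outs = []
        for t_, rep, head in ((p3, self.rep3, self.head3),
                              (p4, self.rep4, self.head4),
                              (p5b, self.rep5, self.head5)):
            y = head(rep(t_))
            n, _, h, w = y.shape
            y = y.reshape(n, 3, 5 + self.cfg.num_classes, h, w)
            outs.append(y.transpose(0, 1, 3, 4, 2))   # (N, 3, H, W, 5+nc)
        return outs


def build_model(cfg: ModelConfig) -> DetectionModel:
    return DetectionModel(cfg)


def _sigmoid(z):
    za = np.exp(-np.abs(z))
    return np.where(z >= 0, 1.0 / (1.0 + za), za / (1.0 + za))


def decode(grids, anchors: AnchorSet, conf_threshold: float = 0.5,
           num_classes: int | None = None, class_names=None,
           image_ids=None, cls_activation: str = "softmax") -> list:
    """Decode raw grids into :class:`Detection` objects.

    Per cell and anchor: center = (sigmoid(txy)*2 - 0.5 + cell)*stride, size
    = (sigmoid(twh)*2)^2 * anchor, score = sigmoid(obj) * max class prob.
    Class probabilities come from a softmax over the class logits by default
    (mutually exclusive species), or per-class sigmoids with
    ``cls_activation="sigmoid"``.  Detections below the confidence threshold
    are dropped.
    """
    groups = anchors.scale_groups
    out = []
    first = grids[0]
    n_batch = first.shape[0] if hasattr(first, "shape") else len(first)
    for g, stride in zip(grids, STRIDES):
        arr = g.numpy() if isinstance(g, Tensor) else np.asarray(g)
        n, na, h, w, _ = arr.shape
        anc = np.asarray(groups[stride])                      # (3, 2)
        xy = _sigmoid(arr[..., 0:2]) * 2.0 - 0.5
        cell_x, cell_y = np.meshgrid(np.arange(w), np.arange(h))
        cx = (xy[..., 0] + cell_x) * stride
        cy = (xy[..., 1] + cell_y) * stride
        wh = (_sigmoid(arr[..., 2:4]) * 2.0) ** 2 * anc[None, :, None, None, :]
        obj = _sigmoid(arr[..., 4])
        if cls_activation == "softmax":
            z = arr[..., 5:] - arr[..., 5:].max(axis=-1, keepdims=True)
            ez = np.exp(z)
            cls = ez / ez.sum(axis=-1, keepdims=True)
        elif cls_activation == "sigmoid":
            cls = _sigmoid(arr[..., 5:])
        else:
            raise ValueError(f"unknown cls_activation {cls_activation!r}")
        best_c = cls.argmax(axis=-1)
        score = obj * np.take_along_axis(cls, best_c[..., None], axis=-1)[..., 0]
        sel = np.argwhere(score >= conf_threshold)
        for b, a, i, j in sel:
            bw, bh = wh[b, a, i, j]
            if bw < 1 or bh < 1:
                continue
            x0, y0 = cx[b, a, i, j] - bw / 2, cy[b, a, i, j] - bh / 2
            label_idx = int(best_c[b, a, i, j])
            label = class_names[label_idx] if class_names else str(label_idx)
            img_id = image_ids[b] if image_ids else str(b)
            out.append(Detection(img_id, label, float(min(1.0, score[b, a, i, j])),
                                 BoundingBox(x0, y0, x0 + bw, y0 + bh, label)))
    return sorted(out, key=lambda d: -d.score)


def save_checkpoint(model: DetectionModel, path) -> Path:
    """Serialize weights (.npz) with a JSON sidecar recording the config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    cfg = model.cfg
    sidecar = {
        "config_hash": cfg.hash(),
        "num_classes": cfg.num_classes,
        "anchors": [list(a) for a in cfg.anchors.anchors],
        "input_size": cfg.input_size,
        "width_scale": cfg.width_scale,
        "use_cbam": cfg.use_cbam,
        "use_coordconv": cfg.use_coordconv,
        "use_kmeans_anchors": cfg.use_kmeans_anchors,
        "cbam_reduction": cfg.cbam_reduction,
        "cbam_merge": cfg.cbam_merge,
        "init_seed": cfg.init_seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_checkpoint(path) -> DetectionModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cfg = ModelConfig(
        num_classes=sidecar["num_classes"],
        anchors=AnchorSet(tuple(map(tuple, sidecar["anchors"]))),
        input_size=sidecar["input_size"], width_scale=sidecar["width_scale"],
        use_cbam=sidecar["use_cbam"], use_coordconv=sidecar["use_coordconv"],
        use_kmeans_anchors=sidecar["use_kmeans_anchors"],
        cbam_reduction=sidecar["cbam_reduction"], cbam_merge=sidecar["cbam_merge"],
        init_seed=sidecar["init_seed"])
    model = DetectionModel(cfg)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
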