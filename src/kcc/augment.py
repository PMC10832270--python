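"""Label-synchronized image augmentation.

Two regimes mirror how small UAV datasets are usually enlarged:

* **offline** — exact geometric ops (flips, quarter-turn rotations,
  transpose) plus photometric ops (contrast, additive Gaussian noise)
  expand a dataset on disk; with the default 10-op policy every input
  yields 10 derived images, an 11x expansion (396 tiles -> 4356).
* **online** — Mosaic (four randomly scaled images spliced on one canvas)
  followed, for a fraction of mosaic outputs, by MixUp (convex pixel blend,
  labels unioned with blend weights), applied stochastically per epoch.

Geometric ops transform box coordinates exactly; photometric ops leave them
untouched.  Pixels are float arrays in [0, 1] throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .voc import BoundingBox, DatasetIndex, ImageAnnotation, write_annotation

__all__ = [
    "LabeledImage", "AugmentPolicy", "DEFAULT_OFFLINE_OPS",
    "flip", "rotate90", "transpose", "adjust_contrast", "add_gaussian_noise",
    "resize", "expand_offline", "mosaic", "mixup", "online_pipeline", "load_labeled_image",
]


@dataclass
class LabeledImage:
    """Pixels (HxWx3 float in [0,1]) plus annotation, with MixUp provenance."""

    pixels: np.ndarray
    ann: ImageAnnotation
    weights: list | None = None          # per-box loss weights in (0, 1]
    provenance: tuple = ("plain",)

    def __post_init__(self):
        h, w = self.pixels.shape[:2]
        if (self.ann.width, self.ann.height) != (w, h):
            raise ValueError(
                f"annotation size {self.ann.width}x{self.ann.height} does not match "
                f"pixel array {w}x{h}")
        if self.weights is not None and len(self.weights) != len(self.ann.boxes):
            raise ValueError("one weight per box required")

    @property
    def box_weights(self) -> list:
        return list(self.weights) if self.weights is not None else [1.0] * len(self.ann.boxes)


def load_labeled_image(ann: ImageAnnotation) -> LabeledImage:
    arr = np.asarray(Image.open(ann.image_path).convert("RGB"), dtype=np.float64) / 255.0
    return LabeledImage(arr, ann)


@dataclass
class AugmentPolicy:
    offline_ops: list = field(default_factory=lambda: list(DEFAULT_OFFLINE_OPS))
    mosaic_ratio: float = 0.8
    mixup_ratio: float = 0.8
    seed: int = 0
    mixup_beta: float = 8.0     # lam ~ Beta(beta, beta); None-like 0 => fixed 0.5
    mosaic_scale_range: tuple = (0.4, 0.8)
    min_area_frac: float = 0.25

    def __post_init__(self):
        if not (0.0 <= self.mosaic_ratio <= 1.0 and 0.0 <= self.mixup_ratio <= 1.0):
            raise ValueError("mosaic/mixup ratios must lie in [0, 1]")


def _with_ann(li: LabeledImage, pixels, boxes, width=None, height=None,
              weights=None, provenance=None) -> LabeledImage:
    ann = ImageAnnotation(li.ann.image_path,
                          width if width is not None else li.ann.width,
                          height if height is not None else li.ann.height,
                          boxes, li.ann.depth)
    return LabeledImage(pixels, ann,
                        li.weights if weights is None else weights,
                        li.provenance if provenance is None else provenance)


def flip(li: LabeledImage, axis: str) -> LabeledImage:
    w, h = li.ann.width, li.ann.height
    if axis == "horizontal":
        pixels = li.pixels[:, ::-1].copy()
        boxes = [replace(b, xmin=w - b.xmax, xmax=w - b.xmin) for b in li.ann.boxes]
    elif axis == "vertical":
        pixels = li.pixels[::-1].copy()
        boxes = [replace(b, ymin=h - b.ymax, ymax=h - b.ymin) for b in li.ann.boxes]
    else:
        raise ValueError(f"unknown flip axis {axis!r}")
    return _with_ann(li, pixels, boxes)


def rotate90(li: LabeledImage, turns: int) -> LabeledImage:
    """Counter-clockwise quarter turns; box coordinates remapped exactly."""
    if turns not in (1, 2, 3):
        raise ValueError("turns must be 1, 2 or 3 (quarter turns only)")
    out = li
    for _ in range(turns):
        w = out.ann.width
        pixels = np.rot90(out.pixels).copy()
        boxes = [BoundingBox(b.ymin, w - b.xmax, b.ymax, w - b.xmin, b.label, b.difficult)
                 for b in out.ann.boxes]
        out = _with_ann(out, pixels, boxes, width=out.ann.height, height=w)
    return out


def transpose(li: LabeledImage) -> LabeledImage:
    """Mirror across the main diagonal (rotate90 then horizontal flip)."""
    return flip(rotate90(li, 1), "horizontal")


def adjust_contrast(li: LabeledImage, factor: float) -> LabeledImage:
    if factor <= 0:
        raise ValueError("contrast factor must be positive")
    mean = li.pixels.mean()
    pixels = np.clip(mean + factor * (li.pixels - mean), 0.0, 1.0)
    return _with_ann(li, pixels, list(li.ann.boxes))


def add_gaussian_noise(li: LabeledImage, sigma: float, seed: int = 0) -> LabeledImage:
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    pixels = np.clip(li.pixels + rng.normal(0.0, sigma, size=li.pixels.shape), 0.0, 1.0)
    return _with_ann(li, pixels, list(li.ann.boxes))


def _nn_resize(pixels: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = pixels.shape[:2]
    ys = np.minimum((np.arange(out_h) * h / out_h).astype(int), h - 1)
    xs = np.minimum((np.arange(out_w) * w / out_w).astype(int), w - 1)
    return pixels[ys][:, xs]


def resize(li: LabeledImage, out_w: int, out_h: int | None = None) -> LabeledImage:
    """Scale image and boxes to the target size (nearest-neighbour pixels)."""
    out_h = out_h or out_w
    sx, sy = out_w / li.ann.width, out_h / li.ann.height
    boxes = [replace(b, xmin=b.xmin * sx, xmax=b.xmax * sx,
                     ymin=b.ymin * sy, ymax=b.ymax * sy) for b in li.ann.boxes]
    return _with_ann(li, _nn_resize(li.pixels, out_h, out_w), boxes,
                     width=out_w, height=out_h)


DEFAULT_OFFLINE_OPS = (
    ("flip", {"axis": "horizontal"}),
    ("flip", {"axis": "vertical"}),
    ("rotate90", {"turns": 1}),
    ("rotate90", {"turns": 2}),
    ("rotate90", {"turns": 3}),
    ("transpose", {}),
    ("contrast", {"factor": 0.7}),
    ("contrast", {"factor": 1.3}),
    ("noise", {"sigma": 0.02}),
    ("noise", {"sigma": 0.05}),
)

_OP_TABLE = {
    "flip": lambda li, seed, axis: flip(li, axis),
    "rotate90": lambda li, seed, turns: rotate90(li, turns),
    "transpose": lambda li, seed: transpose(li),
    "contrast": lambda li, seed, factor: adjust_contrast(li, factor),
    "noise": lambda li, seed, sigma: add_gaussian_noise(li, sigma, seed=seed),
}


def expand_offline(index: DatasetIndex, policy: AugmentPolicy, out_dir) -> DatasetIndex:
    """Materialize originals plus one derived image per (image, op) pair.

    With the default 10-op policy the output has 11x the input images.
    """
    if not policy.offline_ops:
        raise ValueError("offline_ops must be non-empty")
    for name, _ in policy.offline_ops:
        if name not in _OP_TABLE:
            raise ValueError(f"unknown offline op {name!r}; known: {sorted(_OP_TABLE)}")
    out_dir = Path(out_dir)
    img_dir, lbl_dir = out_dir / "images", out_dir / "labels"
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)
    items = []

    def emit(li: LabeledImage, stem: str):
        path = img_dir / f"{stem}.jpg"
        Image.fromarray(np.clip(li.pixels * 255, 0, 255).astype(np.uint8)).save(path, quality=95)
        ann = ImageAnnotation(path, li.ann.width, li.ann.height, list(li.ann.boxes), li.ann.depth)
        write_annotation(ann, lbl_dir / f"{stem}.xml")
        items.append(ann)

    for i, ann in enumerate(index.items):
        li = load_labeled_image(ann)
        stem = ann.image_path.stem
        emit(li, f"{stem}_orig")
        for j, (name, params) in enumerate(policy.offline_ops):
            op_seed = (policy.seed * 1_000_003 + i * 101 + j) % (2 ** 31)
            emit(_OP_TABLE[name](li, op_seed, **params), f"{stem}_{name}{j}")
    return DatasetIndex(items, index.catalog)


def mosaic(four, out_size: int, scale_range=(0.4, 0.8), seed: int = 0,
           min_area_frac: float = 0.25) -> LabeledImage:
    """Splice four randomly scaled labeled images onto one canvas.

    The canvas is split at a random interior point into four quadrants; each
    input is scaled by a factor drawn from ``scale_range`` (relative to the
    canvas) and anchored at the split point.  Boxes are rescaled, translated
    and clipped to their quadrant; a box whose clipped area falls below
    ``min_area_frac`` of its scaled area is dropped.
    """
    if len(four) != 4:
        raise ValueError("mosaic needs exactly four labeled images")
    rng = np.random.default_rng(seed)
    cx = int(rng.uniform(0.3, 0.7) * out_size)
    cy = int(rng.uniform(0.3, 0.7) * out_size)
    canvas = np.full((out_size, out_size, 3), 0.45)
    boxes, weights = [], []
    # per-quadrant paste regions: (x0, y0, x1, y1), inputs anchored at (cx, cy)
    regions = ((0, 0, cx, cy), (cx, 0, out_size, cy),
               (0, cy, cx, out_size), (cx, cy, out_size, out_size))
    corners = ((1, 1), (0, 1), (1, 0), (0, 0))  # which input corner sits at (cx, cy)
    for li, (qx0, qy0, qx1, qy1), (ax, ay) in zip(four, regions, corners):
        s = rng.uniform(*scale_range)
        sw = max(2, int(round(li.ann.width * s * out_size / max(li.ann.width, li.ann.height))))
        sh = max(2, int(round(li.ann.height * s * out_size / max(li.ann.width, li.ann.height))))
        scaled = resize(li, sw, sh)
        # top-left of the scaled image on the canvas
        ox = (qx1 - sw) if ax else qx0
        oy = (qy1 - sh) if ay else qy0
        px0, py0 = max(ox, qx0), max(oy, qy0)
        px1, py1 = min(ox + sw, qx1), min(oy + sh, qy1)
        if px1 <= px0 or py1 <= py0:
            continue
        canvas[py0:py1, px0:px1] = scaled.pixels[py0 - oy:py1 - oy, px0 - ox:px1 - ox]
        for b, w in zip(scaled.ann.boxes, scaled.box_weights):
            nx0, ny0 = b.xmin + ox, b.ymin + oy
            nx1, ny1 = b.xmax + ox, b.ymax + oy
            cx0, cy0 = max(nx0, px0), max(ny0, py0)
            cx1, cy1 = min(nx1, px1), min(ny1, py1)
            if cx1 - cx0 < 2 or cy1 - cy0 < 2:
                continue
            if (cx1 - cx0) * (cy1 - cy0) < min_area_frac * b.area:
                continue
            boxes.append(BoundingBox(cx0, cy0, cx1, cy1, b.label, b.difficult))
            weights.append(w)
    ann = ImageAnnotation(four[0].ann.image_path, out_size, out_size, boxes)
    return LabeledImage(canvas, ann, weights, provenance=("mosaic",))


def mixup(a: LabeledImage, b: LabeledImage, lam: float) -> LabeledImage:
    """Convex blend of two labeled images; labels unioned with weights lam / 1-lam."""
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(f"mixup dimension mismatch: {a.pixels.shape} vs {b.pixels.shape}")
    if not (0.0 < lam < 1.0):
        raise ValueError("lam must lie strictly in (0, 1)")
    pixels = lam * a.pixels + (1.0 - lam) * b.pixels
    boxes = list(a.ann.boxes) + list(b.ann.boxes)
    weights = [w * lam for w in a.box_weights] + [w * (1.0 - lam) for w in b.box_weights]
    ann = ImageAnnotation(a.ann.image_path, a.ann.width, a.ann.height, boxes)
    prov = tuple(dict.fromkeys(a.provenance + b.provenance + ("mixup",)))
    return LabeledImage(pixels, ann, weights, provenance=prov)


def online_pipeline(images, policy: AugmentPolicy, out_size: int = 640, epochs: int = 1):
    """Yield one augmented stream per epoch over ``images`` (LabeledImages).

    Each sample independently enters Mosaic with probability
    ``policy.mosaic_ratio`` (partnered with three random images); each
    mosaic output additionally enters MixUp with probability
    ``policy.mixup_ratio``, blended with a second, freshly built mosaic.
    Samples passing through untouched are resized to the canvas size.
    MixUp is never applied to a non-mosaic sample.
    """
    images = list(images)
    rng = np.random.default_rng(policy.seed)

    def build_mosaic(i):
        partners = [images[int(j)] for j in rng.integers(0, len(images), size=3)]
        return mosaic([images[i]] + partners, out_size, policy.mosaic_scale_range,
                      seed=int(rng.integers(2 ** 31)), min_area_frac=policy.min_area_frac)

    for _ in range(epochs):
        order = rng.permutation(len(images))
        for i in order:
            if rng.random() < policy.mosaic_ratio:
                out = build_mosaic(int(i))
                if rng.random() < policy.mixup_ratio:
                    partner = build_mosaic(int(rng.integers(len(images))))
                    if policy.mixup_beta and policy.mixup_beta > 0:
                        lam = float(np.clip(rng.beta(policy.mixup_beta, policy.mixup_beta),
                                            1e-3, 1 - 1e-3))
                    else:
                        lam = 0.5
                    out = mixup(out, partner, lam)
            else:
                out = resize(images[int(i)], out_size)
            yield out
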