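"""Synthetic canopy scenes: labeled top-down imagery of shelterbelt tree crowns.

Generates 640x640 (configurable) RGB tiles that emulate the statistical
structure of UAV orthophoto crops of a planted shelterbelt: a textured sandy
ground, five crown classes with distinct colour and size distributions,
heavy class imbalance, and controllable crown overlap.  Every drawn crown
yields a tight bounding box, so the scenes exercise annotation I/O, anchor
clustering, augmentation, training and evaluation end to end.

The generator is fully deterministic for a fixed seed.  It emulates the
geometry and label statistics of real canopy imagery, not its radiometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .voc import BoundingBox, ClassCatalog, DatasetIndex, ImageAnnotation, write_annotation

__all__ = [
    "CrownClassSpec", "SceneSpec", "default_scene_spec", "TABLE2_WEIGHTS",
    "generate_scene", "generate_dataset", "sample_box_dims",
]

#: Survey class imbalance (percent of all annotated trees), used as default
#: sampling weights: elm 34.75, poplar 13.43, saxaul 6.55, oleaster 36.90,
#: dead trees 8.36.
TABLE2_WEIGHTS = (34.75, 13.43, 6.55, 36.90, 8.36)


@dataclass(frozen=True)
class CrownClassSpec:
    label: str
    mean_size: float          # crown bounding-box side, px
    size_sd: float
    color_mean: tuple         # RGB 0-255
    color_sd: float
    shape: str = "blob"       # "ellipse" | "blob"
    frequency: float = 1.0    # relative sampling weight

    def __post_init__(self):
        if self.mean_size <= 0:
            raise ValueError("mean_size must be positive")
        if self.frequency < 0:
            raise ValueError("frequency must be non-negative")


@dataclass(frozen=True)
class SceneSpec:
    width: int = 640
    height: int = 640
    classes: tuple = ()
    crowns_per_image: tuple = (6, 13)   # inclusive range
    max_overlap: float = 0.3            # IoU cap between placed crown boxes
    background_color: tuple = (150, 135, 110)
    background_noise_sd: float = 12.0

    def __post_init__(self):
        if self.width < 64 or self.height < 64:
            raise ValueError("scene must be at least 64x64")
        if not all(f >= 0 for f in (c.frequency for c in self.classes)):
            raise ValueError("frequencies must be non-negative")
        if self.classes and not any(c.frequency > 0 for c in self.classes):
            raise ValueError("at least one class needs positive frequency")

    @property
    def catalog(self) -> ClassCatalog:
        return ClassCatalog(tuple(c.label for c in self.classes))


def default_scene_spec(width: int = 640, height: int = 640,
                       size_scale: float = 1.0, **overrides) -> SceneSpec:
    """Scene spec emulating the shelterbelt survey tiles.

    Crown sizes follow each species' habit (large elm/oleaster crowns, small
    saxaul shrubs, small grey-brown dead trees) and class weights follow the
    survey's imbalance.  ``size_scale`` shrinks crowns for small test tiles.
    """
    s = size_scale
    classes = (
        CrownClassSpec("Ulmus pumila", 80 * s, 14 * s, (72, 110, 58), 10.0, "blob",
                       TABLE2_WEIGHTS[0]),
        CrownClassSpec("Populus bolleana", 52 * s, 9 * s, (96, 142, 66), 9.0, "ellipse",
                       TABLE2_WEIGHTS[1]),
        CrownClassSpec("Haloxylon ammodendron", 34 * s, 7 * s, (58, 84, 48), 8.0, "blob",
                       TABLE2_WEIGHTS[2]),
        CrownClassSpec("Elaeagnus angustifolia", 86 * s, 15 * s, (124, 142, 98), 10.0, "blob",
                       TABLE2_WEIGHTS[3]),
        CrownClassSpec("dead trees", 26 * s, 5 * s, (112, 96, 78), 8.0, "blob",
                       TABLE2_WEIGHTS[4]),
    )
    return SceneSpec(width=width, height=height, classes=classes, **overrides)


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3))
    img[:] = spec.background_color
    # low-frequency mottling: a coarse noise field upsampled to tile size
    coarse = rng.normal(0.0, 1.0, size=(max(2, h // 32), max(2, w // 32)))
    ys = np.linspace(0, coarse.shape[0] - 1, h)
    xs = np.linspace(0, coarse.shape[1] - 1, w)
    mott = coarse[ys.astype(int)][:, xs.astype(int)]
    img += (mott * 8.0)[..., None]
    img += rng.normal(0.0, spec.background_noise_sd, size=(h, w, 3))
    return img


def _crown_mask(cx, cy, rx, ry, shape, w, h, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dx = (xx - cx) / rx
    dy = (yy - cy) / ry
    rho = np.sqrt(dx * dx + dy * dy)
    if shape == "ellipse":
        return rho <= 1.0
    # irregular blob: radius modulated by low-order harmonics of the angle
    theta = np.arctan2(dy, dx)
    amps = rng.uniform(0.04, 0.14, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    bound = 1.0 + sum(a * np.cos((k + 2) * theta + p)
                      for k, (a, p) in enumerate(zip(amps, phases)))
    return rho <= bound


def _box_iou(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0:
        return 0.0
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua


def generate_scene(spec: SceneSpec, seed: int):
    """Render one scene; returns ``(uint8 HxWx3 image, ImageAnnotation)``.

    Crowns are placed by rejection sampling against the ``max_overlap`` IoU
    cap; when the tile cannot host the requested count the shortfall is
    recorded on the annotation (``ann.shortfall``).
    """
    rng = np.random.default_rng(seed)
    img = _background(spec, rng)
    lo, hi = spec.crowns_per_image
    n_target = int(rng.integers(lo, hi + 1)) if hi > lo else int(lo)
    weights = np.array([c.frequency for c in spec.classes], dtype=float)
    boxes: list[BoundingBox] = []
    raw_boxes: list[tuple] = []
    placed = 0
    if spec.classes:
        probs = weights / weights.sum()
        for _ in range(n_target):
            for _attempt in range(40):
                cls = spec.classes[int(rng.choice(len(spec.classes), p=probs))]
                side = max(6.0, rng.normal(cls.mean_size, cls.size_sd))
                rx = side / 2.0 * rng.uniform(0.85, 1.15)
                ry = side / 2.0 * rng.uniform(0.85, 1.15)
                cx = rng.uniform(rx * 0.6, spec.width - rx * 0.6)
                cy = rng.uniform(ry * 0.6, spec.height - ry * 0.6)
                cand = (max(0.0, cx - rx * 1.15), max(0.0, cy - ry * 1.15),
                        min(spec.width, cx + rx * 1.15), min(spec.height, cy + ry * 1.15))
                if all(_box_iou(cand, rb) <= spec.max_overlap for rb in raw_boxes):
                    break
            else:
                continue  # could not place this crown
            mask = _crown_mask(cx, cy, rx, ry, cls.shape, spec.width, spec.height, rng)
            if not mask.any():
                continue
            color = rng.normal(cls.color_mean, cls.color_sd)
            yy, xx = np.nonzero(mask)
            # radial shading plus per-pixel speckle for canopy texture
            rad = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
            shade = 1.0 - 0.35 * rad[:, None]
            img[yy, xx] = color * shade + rng.normal(0, 6.0, size=(len(yy), 3))
            x0, x1 = float(xx.min()), float(xx.max() + 1)
            y0, y1 = float(yy.min()), float(yy.max() + 1)
            if x1 - x0 < 2 or y1 - y0 < 2:
                continue
            boxes.append(BoundingBox(x0, y0, x1, y1, cls.label))
            raw_boxes.append((x0, y0, x1, y1))
            placed += 1
    arr = np.clip(img, 0, 255).astype(np.uint8)
    ann = ImageAnnotation(Path(f"scene_{seed}.jpg"), spec.width, spec.height, boxes)
    ann.shortfall = n_target - placed
    return arr, ann


def generate_dataset(n_images: int, spec: SceneSpec, seed: int, out_dir) -> DatasetIndex:
    """Write ``n_images`` JPEG tiles plus VOC XML labels under ``out_dir``."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    img_dir, lbl_dir = out_dir / "images", out_dir / "labels"
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2 ** 31 - 1, size=n_images)
    items = []
    for i, s in enumerate(child_seeds):
        arr, ann = generate_scene(spec, int(s))
        stem = f"scene_{i:05d}"
        path = img_dir / f"{stem}.jpg"
        Image.fromarray(arr).save(path, quality=95)
        ann.image_path = path
        write_annotation(ann, lbl_dir / f"{stem}.xml")
        items.append(ann)
    return DatasetIndex(items, spec.catalog)


def sample_box_dims(mixture, n: int, seed: int) -> list:
    """Sample ``n`` (w, h) pairs from a Gaussian mixture over box dimensions.

    ``mixture`` is a list of ``(mean_w, mean_h, sd, weight)`` components;
    used to feed anchor clustering with controllable ground truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    comps = list(mixture)
    if any(c[2] < 0 for c in comps):
        raise ValueError("component sd must be non-negative")
    w = np.array([c[3] for c in comps], dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must normalize")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(comps), size=n, p=w / w.sum())
    out = []
    for i in idx:
        mw, mh, sd, _ = comps[i]
        dw = max(1.0, rng.normal(mw, sd))
        dh = max(1.0, rng.normal(mh, sd))
        out.append((dw, dh))
    return out
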