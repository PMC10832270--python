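"""Pascal VOC annotation I/O, dataset indexing, splitting and summaries.

Annotations follow the labelImg dialect of the VOC XML schema.  On disk the
box coordinates are 1-based and inclusive; internally every box is stored
0-based and half-open, so ``width = xmax - xmin`` holds without off-by-one
caveats.  The conversion is inverted exactly on write, making
read -> write -> read an identity.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULT_SPECIES", "ClassCatalog", "BoundingBox", "ImageAnnotation",
    "DatasetIndex", "read_annotation", "write_annotation", "split_dataset",
    "summarize", "UnknownLabelError",
]

#: The five crown classes of the shelterbelt survey, in catalog order.
DEFAULT_SPECIES = (
    "Ulmus pumila",
    "Populus bolleana",
    "Haloxylon ammodendron",
    "Elaeagnus angustifolia",
    "dead trees",
)


class UnknownLabelError(ValueError):
    pass


@dataclass(frozen=True)
class ClassCatalog:
    """Ordered, unique class labels with contiguous integer ids."""

    names: tuple = DEFAULT_SPECIES

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        if len(set(self.names)) != len(self.names):
            raise ValueError("class labels must be unique")
        if not self.names:
            raise ValueError("catalog must contain at least one label")

    def id_of(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise UnknownLabelError(
                f"unknown label {label!r}; valid labels: {list(self.names)}") from None

    def __len__(self):
        return len(self.names)

    def __contains__(self, label):
        return label in self.names


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based half-open pixel coordinates."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    label: str
    difficult: bool = False

    def __post_init__(self):
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def clipped(self, width: float, height: float) -> "BoundingBox":
        return replace(self, xmin=max(0.0, self.xmin), ymin=max(0.0, self.ymin),
                       xmax=min(float(width), self.xmax), ymax=min(float(height), self.ymax))


@dataclass
class ImageAnnotation:
    """One image and its labeled boxes — the unit flowing through the toolkit."""

    image_path: Path
    width: int
    height: int
    boxes: list = field(default_factory=list)
    depth: int = 3

    def __post_init__(self):
        self.image_path = Path(self.image_path)
        for b in self.boxes:
            self.validate_box(b)

    def validate_box(self, b: BoundingBox):
        if not (0 <= b.xmin < b.xmax <= self.width and 0 <= b.ymin < b.ymax <= self.height):
            raise ValueError(f"box {b} outside image bounds {self.width}x{self.height}")


@dataclass
class DatasetIndex:
    items: list
    catalog: ClassCatalog = field(default_factory=ClassCatalog)

    def __post_init__(self):
        for ann in self.items:
            for b in ann.boxes:
                if b.label not in self.catalog:
                    raise UnknownLabelError(
                        f"label {b.label!r} in {ann.image_path} not in catalog")

    def __len__(self):
        return len(self.items)

    @classmethod
    def from_directory(cls, root, catalog: ClassCatalog | None = None,
                       permissive: bool = False) -> "DatasetIndex":
        """Index a `images/ labels/` layout; labels may also sit beside images."""
        root = Path(root)
        label_dir = root / "labels" if (root / "labels").is_dir() else root
        catalog = catalog or ClassCatalog()
        items = [read_annotation(p, catalog, permissive=permissive)
                 for p in sorted(label_dir.glob("*.xml"))]
        if permissive:
            extra = sorted({b.label for ann in items for b in ann.boxes} - set(catalog.names))
            if extra:
                catalog = ClassCatalog(catalog.names + tuple(extra))
        return cls(items, catalog)


def read_annotation(xml_path, catalog: ClassCatalog | None = None,
                    permissive: bool = False) -> ImageAnnotation:
    """Parse one VOC XML file into an :class:`ImageAnnotation`.

    Raises a parse error naming the file on malformed XML; unknown labels
    raise :class:`UnknownLabelError` unless ``permissive`` is set.
    """
    xml_path = Path(xml_path)
    try:
        tree = ET.parse(xml_path)
    except ET.ParseError as e:
        raise ET.ParseError(f"malformed VOC XML in {xml_path}: {e}") from e
    root = tree.getroot()
    size = root.find("size")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    depth = int(size.findtext("depth", default="3"))
    folder = root.findtext("folder", default="")
    filename = root.findtext("filename", default=xml_path.stem + ".jpg")
    image_path = xml_path.parent.parent / folder / filename if folder else xml_path.parent / filename

    boxes = []
    for obj in root.findall("object"):
        label = obj.findtext("name")
        if catalog is not None and label not in catalog and not permissive:
            raise UnknownLabelError(
                f"{xml_path}: unknown label {label!r}; valid labels: {list(catalog.names)}")
        bb = obj.find("bndbox")
        # VOC/labelImg stores 1-based inclusive pixel indices.
        xmin = float(bb.findtext("xmin")) - 1.0
        ymin = float(bb.findtext("ymin")) - 1.0
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        difficult = obj.findtext("difficult", default="0").strip() == "1"
        boxes.append(BoundingBox(xmin, ymin, xmax, ymax, label, difficult))
    return ImageAnnotation(image_path, width, height, boxes, depth)


def write_annotation(ann: ImageAnnotation, out_path) -> Path:
    """Write VOC XML readable by :func:`read_annotation`; round-trip exact."""
    out_path = Path(out_path)
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = ann.image_path.parent.name
    ET.SubElement(root, "filename").text = ann.image_path.name
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.width)
    ET.SubElement(size, "height").text = str(ann.height)
    ET.SubElement(size, "depth").text = str(ann.depth)
    for b in ann.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = b.label
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "1" if b.difficult else "0"
        bb = ET.SubElement(obj, "bndbox")

        def fmt(v: float) -> str:
            return str(int(v)) if float(v).is_integer() else repr(float(v))

        ET.SubElement(bb, "xmin").text = fmt(b.xmin + 1.0)
        ET.SubElement(bb, "ymin").text = fmt(b.ymin + 1.0)
        ET.SubElement(bb, "xmax").text = fmt(b.xmax)
        ET.SubElement(bb, "ymax").text = fmt(b.ymax)
    ET.indent(root)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    ET.ElementTree(root).write(out_path, encoding="unicode")
    return out_path


def _largest_remainder(n: int, ratios) -> list:
    """Integer split sizes of n by largest-remainder rounding of n*ratio."""
    exact = [n * r for r in ratios]
    sizes = [math.floor(e) for e in exact]
    short = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: exact[i] - sizes[i], reverse=True)
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def split_dataset(index: DatasetIndex, ratios=(0.7, 0.2, 0.1), seed: int = 0,
                  counts=None):
    """Random disjoint train/val/test partition covering every item.

    Ratio mode sizes the splits by largest-remainder rounding; counts mode
    takes explicit sizes (they must sum to ``len(index)``).  Deterministic
    for a fixed seed; the sizes never depend on the seed.
    """
    n = len(index)
    if counts is not None:
        sizes = list(counts)
        if sum(sizes) != n:
            raise ValueError(f"counts {sizes} do not sum to dataset size {n}")
    else:
        if any(r <= 0 for r in ratios):
            raise ValueError("ratios must be positive")
        if abs(sum(ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
        sizes = _largest_remainder(n, ratios)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    out, start = [], 0
    for s in sizes:
        sel = sorted(perm[start:start + s])
        out.append(DatasetIndex([index.items[i] for i in sel], index.catalog))
        start += s
    return tuple(out)


def summarize(index: DatasetIndex) -> dict:
    """Per-class box counts and percentage proportions (2-decimal rounding)."""
    counts = {name: 0 for name in index.catalog.names}
    for ann in index.items:
        for b in ann.boxes:
            counts[b.label] = counts.get(b.label, 0) + 1
    total = sum(counts.values())
    empty = total == 0
    proportions = {name: (0.0 if empty else round(100.0 * c / total, 2))
                   for name, c in counts.items()}
    return {
        "counts": counts,
        "total": total,
        "proportions_pct": proportions,
        "n_images": len(index),
        "empty": empty,
    }
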