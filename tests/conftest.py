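import numpy as np
import pytest

from kcc import nd
from kcc.scenes import default_scene_spec, generate_dataset
from kcc.voc import BoundingBox, ClassCatalog, ImageAnnotation


@pytest.fixture(autouse=True)
def _float64_default():
    """Gradient checks need float64; restore it around every test."""
    nd.set_default_dtype(np.float64)
    yield
    nd.set_default_dtype(np.float64)


@pytest.fixture(scope="session")
def catalog():
    return ClassCatalog()


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Ten small rendered scenes with VOC labels on disk (shared, read-only)."""
    out = tmp_path_factory.mktemp("tiny_scenes")
    spec = default_scene_spec(128, 128, size_scale=0.4, crowns_per_image=(2, 5),
                              max_overlap=0.15)
    return generate_dataset(10, spec, 7, out)


def random_annotation(rng, width=640, height=640, max_boxes=8, catalog=None):
    names = (catalog or ClassCatalog()).names
    n = int(rng.integers(0, max_boxes + 1))
    boxes = []
    for _ in range(n):
        w = float(rng.integers(2, width // 2))
        h = float(rng.integers(2, height // 2))
        x0 = float(rng.integers(0, width - int(w)))
        y0 = float(rng.integers(0, height - int(h)))
        boxes.append(BoundingBox(x0, y0, x0 + w, y0 + h,
                                 names[int(rng.integers(len(names)))]))
    return ImageAnnotation(f"img_{rng.integers(1 << 30)}.jpg", width, height, boxes)
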