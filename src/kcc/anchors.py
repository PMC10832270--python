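"""Anchor priors from ground-truth box dimensions via K-means++ clustering.

Single-stage detectors regress boxes against a fixed set of (width, height)
priors; priors clustered from the training distribution match targets far
better than hand-set ones.  Two ingredients are configurable because the
method leaves them open:

* distance between two box shapes — ``"iou"`` (1 - IoU of corner-aligned
  boxes, the YOLO community convention) or ``"euclidean"``;
* seeding — ``"farthest"`` (each new centre is the point farthest from the
  existing centres; deterministic after the first pick) or ``"dsquared"``
  (classical K-means++ D^2 sampling).

Lloyd iterations then alternate nearest-centre assignment with arithmetic
mean re-centering until the assignment reaches a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AnchorSet", "box_distance", "kmeanspp_seed", "cluster_anchors", "assign_scales",
           "PAPER_ANCHORS"]

#: The 9 priors reported for the shelterbelt survey dataset (stride order
#: small to large after area sort); useful as a realistic default.
PAPER_ANCHORS = ((60, 76), (110, 81), (91, 92), (84, 139), (141, 87),
                 (125, 125), (185, 132), (135, 189), (210, 205))

STRIDES = (8, 16, 32)


@dataclass(frozen=True)
class AnchorSet:
    """k (w, h) priors sorted by area, grouped 3-per-scale for strides 8/16/32."""

    anchors: tuple

    def __post_init__(self):
        anchors = tuple((float(w), float(h)) for w, h in self.anchors)
        if any(w <= 0 or h <= 0 for w, h in anchors):
            raise ValueError("anchor dims must be positive")
        anchors = tuple(sorted(anchors, key=lambda wh: wh[0] * wh[1]))
        object.__setattr__(self, "anchors", anchors)

    def __len__(self):
        return len(self.anchors)

    @property
    def scale_groups(self) -> dict:
        return assign_scales(self)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.anchors, dtype=float)


def _dist_matrix(dims: np.ndarray, centers: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise distances, shape (len(dims), len(centers))."""
    if metric == "iou":
        inter = (np.minimum(dims[:, None, 0], centers[None, :, 0])
                 * np.minimum(dims[:, None, 1], centers[None, :, 1]))
        union = (dims[:, 0] * dims[:, 1])[:, None] + (centers[:, 0] * centers[:, 1])[None, :] - inter
        return 1.0 - inter / union
    if metric == "euclidean":
        return np.sqrt(((dims[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
    raise ValueError(f"unknown metric {metric!r}; choose 'iou' or 'euclidean'")


def box_distance(a, b, metric: str = "iou") -> float:
    """Distance between two (w, h) box shapes; zero iff identical dims."""
    return float(_dist_matrix(np.array([a], float), np.array([b], float), metric)[0, 0])


def _canonical(dims) -> np.ndarray:
    arr = np.asarray([(float(w), float(h)) for w, h in dims])
    if arr.size == 0 or (arr <= 0).any():
        raise ValueError("box dims must be positive and non-empty")
    # sort lexicographically so the result is independent of enumeration order
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    return arr[order]


def kmeanspp_seed(dims, k: int, mode: str = "farthest", metric: str = "iou",
                  seed: int = 0) -> np.ndarray:
    """Pick k initial cluster centres from the box dimensions.

    ``farthest``: after a random first pick, each next centre is the point
    maximising the distance to its nearest existing centre.  ``dsquared``:
    next centre sampled with probability proportional to that distance
    squared.
    """
    arr = _canonical(dims)
    distinct = np.unique(arr, axis=0)
    if k > len(distinct):
        raise ValueError(f"k={k} exceeds number of distinct box dims ({len(distinct)})")
    rng = np.random.default_rng(seed)
    centers = [arr[int(rng.integers(len(arr)))]]
    while len(centers) < k:
        d = _dist_matrix(arr, np.asarray(centers), metric).min(axis=1)
        if mode == "farthest":
            nxt = int(np.argmax(d))
        elif mode == "dsquared":
            p = d ** 2
            if p.sum() == 0:
                raise ValueError("cannot seed: all points coincide with centres")
            nxt = int(rng.choice(len(arr), p=p / p.sum()))
        else:
            raise ValueError(f"unknown mode {mode!r}; choose 'farthest' or 'dsquared'")
        centers.append(arr[nxt])
    return np.asarray(centers)


def cluster_anchors(dims, k: int = 9, metric: str = "iou", mode: str = "farthest",
                    max_iter: int = 300, seed: int = 0,
                    return_history: bool = False):
    """Cluster box dimensions into an :class:`AnchorSet` of k priors.

    Lloyd iterations stop at an assignment fixed point (or ``max_iter``).
    An emptied cluster is reseeded at the point farthest from all centres.
    Returns the anchor set, optionally with the per-iteration mean
    nearest-centre distance (monotone non-increasing).
    """
    arr = _canonical(dims)
    if len(arr) < k:
        raise ValueError(f"need at least k={k} boxes, got {len(arr)}")
    centers = kmeanspp_seed(arr, k, mode=mode, metric=metric, seed=seed).copy()
    history = []
    assign = None
    best_obj, best_centers = np.inf, centers.copy()
    for _ in range(max_iter):
        d = _dist_matrix(arr, centers, metric)
        new_assign = d.argmin(axis=1)
        obj = float(d[np.arange(len(arr)), new_assign].mean())
        if obj < best_obj:
            best_obj, best_centers = obj, centers.copy()
        # mean recentering is not strictly a descent step under the IoU
        # objective, so iterate to the assignment fixed point but keep (and
        # report) the best iterate seen — monotone by construction
        history.append(best_obj)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = arr[assign == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:  # reseed an emptied cluster at the farthest point
                far = _dist_matrix(arr, centers, metric).min(axis=1)
                centers[j] = arr[int(np.argmax(far))]
    centers = best_centers
    anchor_set = AnchorSet(tuple(map(tuple, centers)))
    return (anchor_set, history) if return_history else anchor_set


def assign_scales(anchor_set: AnchorSet) -> dict:
    """Group the (area-sorted) anchors 3-per-scale onto strides 8/16/32."""
    k = len(anchor_set)
    if k % 3:
        raise ValueError(f"anchor count {k} not divisible by 3")
    per = k // 3
    return {stride: anchor_set.anchors[i * per:(i + 1) * per]
            for i, stride in enumerate(STRIDES)}
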