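"""Per-item food masks.

Two routes produce a :class:`SegmentationMap`:

* :func:`region_grow_merge` — semi-automatic seeded region growing and
  merging; user strokes are the seeds, growth is a colour-similarity flood
  in CIELAB, followed by merging of adjacent unclaimed colour blobs.
* :func:`auto_segment` — a pluggable class-agnostic instance-segmenter
  interface with a classical colour-clustering fallback backend.

Plus the two-number segmentation score :func:`fscore_min_sum` (minimum
per-item F-score, and the F-score of the pooled food-vs-background pixels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab
from skimage.draw import line as draw_line

_STRUCT4 = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


class SegmentationError(ValueError):
    pass


class BackendError(RuntimeError):
    """An automatic-segmentation backend failed."""


@dataclass(frozen=True)
class SegmentationMap:
    """Integer label image: 0 = background, 1..N = food items.

    Labels are always contiguous; use :meth:`from_labels` to normalize an
    arbitrary label image.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise SegmentationError("label image must be 2-D")
        lab = lab.astype(np.int32, copy=True)
        present = np.unique(lab)
        present = present[present > 0]
        n = len(present)
        if n and not np.array_equal(present, np.arange(1, n + 1)):
            raise SegmentationError(
                f"labels must be contiguous 1..N, got {present.tolist()}"
            )
        lab.setflags(write=False)
        object.__setattr__(self, "labels", lab)

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "SegmentationMap":
        """Relabel an arbitrary non-negative label image contiguously."""
        lab = np.asarray(labels).astype(np.int64)
        present = np.unique(lab)
        present = present[present > 0]
        remap = np.zeros(int(lab.max()) + 1 if lab.size else 1, dtype=np.int32)
        remap[present] = np.arange(1, len(present) + 1, dtype=np.int32)
        return cls(np.where(lab > 0, remap[np.maximum(lab, 0)], 0))

    @property
    def shape(self):
        return self.labels.shape

    @property
    def n_items(self) -> int:
        return int(self.labels.max())

    def mask(self, item: int) -> np.ndarray:
        return self.labels == item

    def bounding_box(self, item: int):
        """(row_min, row_max, col_min, col_max), inclusive."""
        rows, cols = np.nonzero(self.labels == item)
        if len(rows) == 0:
            raise SegmentationError(f"item {item} has no pixels")
        return int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max())


@dataclass(frozen=True)
class SeedStroke:
    """Rasterized user stroke marking one food item."""

    item_id: int
    pixels: np.ndarray  # (N, 2) integer (x, y)

    def __post_init__(self) -> None:
        px = np.atleast_2d(np.asarray(self.pixels, dtype=np.int64))
        if px.shape[1] != 2 or len(px) == 0:
            raise SegmentationError("a stroke needs >= 1 (x, y) pixel")
        object.__setattr__(self, "pixels", px)


def stroke_from_polyline(item_id: int, points: Sequence, image_shape) -> SeedStroke:
    """Rasterize a polyline of (x, y) vertices into a SeedStroke."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.int64))
    h, w = image_shape[:2]
    xs, ys = [], []
    for a, b in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(int(a[1]), int(a[0]), int(b[1]), int(b[0]))
        xs.append(cc)
        ys.append(rr)
    if len(pts) == 1:
        xs, ys = [pts[:, 0]], [pts[:, 1]]
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if (x < 0).any() or (y < 0).any() or (x >= w).any() or (y >= h).any():
        raise SegmentationError(f"stroke for item {item_id} leaves the image")
    return SeedStroke(item_id, np.stack([x, y], axis=1))


@dataclass(frozen=True)
class GrowParams:
    """Tuning knobs of the seeded grow-and-merge segmenter.

    ``tau_grow``/``tau_merge`` are Euclidean distances in CIELAB (a roughly
    perceptually uniform space); growth and adjacency use 4-connectivity.
    """

    tau_grow: float = 14.0
    tau_merge: float = 10.0
    max_merge_rounds: int = 10


def _validate_seeds(seeds: Sequence[SeedStroke], shape) -> dict:
    h, w = shape[:2]
    by_item: dict[int, list] = {}
    for s in seeds:
        px = s.pixels
        if (px[:, 0] < 0).any() or (px[:, 0] >= w).any() or (px[:, 1] < 0).any() or (px[:, 1] >= h).any():
            raise SegmentationError(f"seed stroke for item {s.item_id} leaves the image")
        by_item.setdefault(s.item_id, []).append(px)
    claimed = np.full((h, w), -1, dtype=np.int64)
    for item_id, chunks in by_item.items():
        for px in chunks:
            prev = claimed[px[:, 1], px[:, 0]]
            clash = prev[(prev >= 0) & (prev != item_id)]
            if len(clash):
                raise SegmentationError(
                    f"seed strokes overlap: items {int(clash[0])} and {item_id}"
                )
            claimed[px[:, 1], px[:, 0]] = item_id
    return {k: np.vstack(v) for k, v in by_item.items()}


def region_grow_merge(
    image: np.ndarray,
    seeds: Sequence[SeedStroke],
    params: GrowParams | None = None,
) -> SegmentationMap:
    """Grow each seed stroke by colour similarity, then merge leftovers.

    Each item's region is the 4-connected component (containing its seeds)
    of pixels whose CIELAB distance to the item's seed-mean colour is below
    ``tau_grow``. Pixels reachable by several items go to the closest item
    in colour. Remaining unclaimed blobs are merged into an adjacent item
    when their mean colour is within ``tau_merge``; anything left is
    background.
    """
    if params is None:
        params = GrowParams()
    if len(seeds) == 0:
        raise SegmentationError("at least one seed stroke is required")
    img = np.asarray(image, dtype=float)
    by_item = _validate_seeds(seeds, img.shape)
    lab = rgb2lab(np.clip(img, 0.0, 1.0))
    h, w = lab.shape[:2]

    item_ids = sorted(by_item)
    claim_dist = np.full((h, w), np.inf)
    claim = np.zeros((h, w), dtype=np.int64)  # 0 = unclaimed, else 1..N
    means = {}
    for n, item_id in enumerate(item_ids, start=1):
        px = by_item[item_id]
        mean = lab[px[:, 1], px[:, 0]].mean(axis=0)
        means[n] = mean
        dist = np.linalg.norm(lab - mean, axis=2)
        grown = dist < params.tau_grow
        comp, _ = ndimage.label(grown, structure=_STRUCT4)
        seed_comps = np.unique(comp[px[:, 1], px[:, 0]])
        seed_comps = seed_comps[seed_comps > 0]
        region = np.isin(comp, seed_comps) if len(seed_comps) else np.zeros_like(grown)
        region[px[:, 1], px[:, 0]] = True
        better = region & (dist < claim_dist)
        claim[better] = n
        claim_dist[better] = dist[better]
    # a stroke's pixels always end inside its own item's region
    for n, item_id in enumerate(item_ids, start=1):
        px = by_item[item_id]
        claim[px[:, 1], px[:, 0]] = n

    # merge unclaimed colour blobs into adjacent items
    for _ in range(params.max_merge_rounds):
        unclaimed, n_blobs = ndimage.label(claim == 0, structure=_STRUCT4)
        merged_any = False
        for blob in range(1, n_blobs + 1):
            blob_mask = unclaimed == blob
            blob_mean = lab[blob_mask].mean(axis=0)
            ring = ndimage.binary_dilation(blob_mask, structure=_STRUCT4) & ~blob_mask
            neighbors = np.unique(claim[ring])
            neighbors = neighbors[neighbors > 0]
            best, best_d = 0, np.inf
            for n in neighbors:
                d = float(np.linalg.norm(blob_mean - means[n]))
                if d < best_d:
                    best, best_d = int(n), d
            if best and best_d < params.tau_merge:
                claim[blob_mask] = best
                merged_any = True
        if not merged_any:
            break
    return SegmentationMap(claim)


def _fallback_color_clusters(image: np.ndarray, n_clusters: int = 6, min_area: int = 50):
    """Classical backend: CIELAB k-means + connected components."""
    from scipy.cluster.vq import kmeans2

    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    lab = rgb2lab(img)
    flat = lab.reshape(-1, 3)
    k = min(n_clusters, max(2, len(np.unique(flat.round(0), axis=0))))
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        # empty clusters are fine here: uniform images have < k colours
        warnings.simplefilter("ignore")
        _, assign = kmeans2(flat, k, minit="++", seed=0)
    assign = assign.reshape(lab.shape[:2])
    border = np.concatenate(
        [assign[0], assign[-1], assign[:, 0], assign[:, -1]]
    )
    background = np.bincount(border).argmax()
    out = np.zeros(assign.shape, dtype=np.int64)
    next_label = 1
    for c in range(k):
        if c == background:
            continue
        comp, n = ndimage.label(assign == c, structure=_STRUCT4)
        for i in range(1, n + 1):
            m = comp == i
            if m.sum() >= min_area:
                out[m] = next_label
                next_label += 1
    return out


def auto_segment(
    image: np.ndarray,
    backend: Callable[[np.ndarray], np.ndarray] | None = None,
) -> SegmentationMap:
    """Class-agnostic instance segmentation via a pluggable backend.

    ``backend(image)`` must return a non-negative integer label image; the
    result is relabelled contiguously. The default backend clusters colours
    and splits them into connected components (a stand-in for a learned
    instance segmenter, which plugs in through the same interface).
    """
    fn = backend if backend is not None else _fallback_color_clusters
    name = getattr(fn, "__name__", type(fn).__name__)
    try:
        raw = fn(np.asarray(image, dtype=float))
    except Exception as exc:  # propagate with backend name
        raise BackendError(f"segmentation backend '{name}' failed: {exc}") from exc
    raw = np.asarray(raw)
    if raw.shape[:2] != np.asarray(image).shape[:2]:
        raise BackendError(f"backend '{name}' returned wrong-shaped labels")
    return SegmentationMap.from_labels(raw)


def _f1(tp: float, n_pred: float, n_truth: float) -> float:
    if n_pred == 0 or n_truth == 0 or tp == 0:
        return 0.0
    p = tp / n_pred
    r = tp / n_truth
    return 2.0 * p * r / (p + r)


def fscore_min_sum(pred: SegmentationMap, truth: SegmentationMap):
    """(Fmin, Fsum) segmentation scores in [0, 1].

    Predicted items are matched one-to-one to ground-truth items greedily by
    pixel overlap. Fmin is the minimum per-truth-item F-score (unmatched
    truth items score 0); Fsum is the F-score of the pooled food pixels,
    ignoring item identity. Unmatched predicted items therefore hurt Fsum
    (as precision errors) but do not define an Fmin term.
    """
    if pred.shape != truth.shape:
        raise SegmentationError("prediction and truth sizes differ")
    nt = truth.n_items
    if nt == 0:
        raise SegmentationError("ground truth has no items")
    np_ = pred.n_items
    p = pred.labels.ravel()
    t = truth.labels.ravel()
    overlap = np.zeros((np_ + 1, nt + 1), dtype=np.int64)
    joint = p * (nt + 1) + t
    counts = np.bincount(joint, minlength=(np_ + 1) * (nt + 1))
    overlap.flat[: len(counts)] = counts
    pred_sizes = overlap.sum(axis=1)
    truth_sizes = overlap.sum(axis=0)

    pair = overlap[1:, 1:].astype(float).copy()
    fs = []
    while pair.size and pair.max() > 0:
        i, j = np.unravel_index(np.argmax(pair), pair.shape)
        tp = pair[i, j]
        fs.append(_f1(tp, pred_sizes[i + 1], truth_sizes[j + 1]))
        pair[i, :] = -1
        pair[:, j] = -1
    fmin = min(fs) if len(fs) == nt else 0.0

    tp_sum = int(((p > 0) & (t > 0)).sum())
    fsum = _f1(tp_sum, int((p > 0).sum()), int((t > 0).sum()))
    return float(fmin), float(fsum)
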