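"""Three-level hierarchical food recognition.

A food category lives in a three-level taxonomy (hyper1 > hyper2 > fine).
The classifier is one shared backbone with three parallel softmax heads,
one per level, trained jointly with summed cross-entropies. At inference a
weighted rule picks the level to report: normally the fine-grained tag,
falling back to a hyper category when the fine-grained confidence is low
(unknown-food handling).

The desk-scale backbone is a small fully-connected network over pooled
colour statistics, written in plain numpy so the package has no deep
learning dependency; any callable producing fixed-length features can be
plugged in instead (a production system would use a large pretrained CNN
here — the heads and the training recipe are unchanged).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LEVELS = ("hyper1", "hyper2", "fine")


class TaxonomyError(ValueError):
    pass


@dataclass(frozen=True)
class FoodTaxonomy:
    """Three-level hierarchy over fine-grained food categories.

    Every fine-grained category has exactly one hyper2 parent, every hyper2
    exactly one hyper1 parent. ``nutrient_keys`` maps each category name
    (at any level) to a key of the nutrient table.
    """

    fine_names: tuple
    hyper2_names: tuple
    hyper1_names: tuple
    fine_to_hyper2: dict      # fine name -> hyper2 name
    hyper2_to_hyper1: dict    # hyper2 name -> hyper1 name
    nutrient_keys: dict       # fine name -> nutrient table key

    def __post_init__(self) -> None:
        if not (len(self.hyper1_names) <= len(self.hyper2_names) <= len(self.fine_names)):
            raise TaxonomyError("level sizes must satisfy |hyper1| <= |hyper2| <= |fine|")
        for f in self.fine_names:
            h2 = self.fine_to_hyper2.get(f)
            if h2 not in self.hyper2_names:
                raise TaxonomyError(f"fine category '{f}' has no valid hyper2 parent")
            if self.hyper2_to_hyper1.get(h2) not in self.hyper1_names:
                raise TaxonomyError(f"hyper2 category '{h2}' has no valid hyper1 parent")

    @property
    def level_sizes(self):
        """(|hyper1|, |hyper2|, |fine|) — head widths, coarse to fine."""
        return (len(self.hyper1_names), len(self.hyper2_names), len(self.fine_names))

    def path(self, fine_index: int):
        fine = self.fine_names[fine_index]
        h2 = self.fine_to_hyper2[fine]
        return (self.hyper2_to_hyper1[h2], h2, fine)

    def hyper2_index_of_fine(self, fine_index: int) -> int:
        return self.hyper2_names.index(self.fine_to_hyper2[self.fine_names[fine_index]])

    def hyper1_index_of_fine(self, fine_index: int) -> int:
        h2 = self.fine_to_hyper2[self.fine_names[fine_index]]
        return self.hyper1_names.index(self.hyper2_to_hyper1[h2])

    def name_at(self, level: str, index: int) -> str:
        return {
            "hyper1": self.hyper1_names,
            "hyper2": self.hyper2_names,
            "fine": self.fine_names,
        }[level][index]

    def nutrient_key(self, category: str) -> str:
        """Nutrient-table key for a category at any level (defaults to the
        category name itself for hyper levels)."""
        return self.nutrient_keys.get(category, category)

    def write(self, path) -> None:
        rows = [
            {
                "fine": f,
                "hyper2": self.fine_to_hyper2[f],
                "hyper1": self.hyper2_to_hyper1[self.fine_to_hyper2[f]],
                "nutrient_key": self.nutrient_keys.get(f, f),
            }
            for f in self.fine_names
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def load_taxonomy(path) -> FoodTaxonomy:
    """Read the CSV dialect ``fine,hyper2,hyper1,nutrient_key``."""
    df = pd.read_csv(path, dtype=str)
    required = {"fine", "hyper2", "hyper1"}
    if not required.issubset(df.columns):
        raise TaxonomyError(f"taxonomy file must have columns {sorted(required)}")
    if "nutrient_key" not in df.columns:
        df["nutrient_key"] = df["fine"]
    dup = df["fine"][df["fine"].duplicated()]
    if len(dup):
        raise TaxonomyError(f"duplicate fine-grained categories: {dup.tolist()}")
    for col in ("fine", "hyper2", "hyper1"):
        bad = df.index[df[col].isna() | (df[col].astype(str).str.strip() == "")]
        if len(bad):
            raise TaxonomyError(f"row {int(bad[0]) + 1}: empty '{col}' entry")
    f2h2, h22h1 = {}, {}
    for i, row in df.iterrows():
        f2h2[row["fine"]] = row["hyper2"]
        prev = h22h1.get(row["hyper2"])
        if prev is not None and prev != row["hyper1"]:
            raise TaxonomyError(
                f"row {i + 1}: hyper2 '{row['hyper2']}' has two hyper1 parents"
            )
        h22h1[row["hyper2"]] = row["hyper1"]
    nutrient = {row["fine"]: row["nutrient_key"] for _, row in df.iterrows()}
    # stable first-appearance order
    return FoodTaxonomy(
        fine_names=tuple(df["fine"]),
        hyper2_names=tuple(dict.fromkeys(df["hyper2"])),
        hyper1_names=tuple(dict.fromkeys(df["hyper1"])),
        fine_to_hyper2=f2h2,
        hyper2_to_hyper1=h22h1,
        nutrient_keys=nutrient,
    )


def toy_taxonomy(n_fine: int = 12, n_hyper2: int = 6, n_hyper1: int = 3) -> FoodTaxonomy:
    """Small synthetic taxonomy with evenly distributed parents."""
    fine = tuple(f"food_{i:02d}" for i in range(n_fine))
    h2 = tuple(f"group_{i}" for i in range(n_hyper2))
    h1 = tuple(f"super_{i}" for i in range(n_hyper1))
    f2h2 = {f: h2[i % n_hyper2] for i, f in enumerate(fine)}
    h22h1 = {g: h1[i % n_hyper1] for i, g in enumerate(h2)}
    return FoodTaxonomy(fine, h2, h1, f2h2, h22h1, {f: f for f in fine})


# ---------------------------------------------------------------------------
# features / model


def color_stat_features(images: np.ndarray, grid: int = 2) -> np.ndarray:
    """Pooled colour statistics: per-cell means on a ``grid x grid`` split
    plus global mean and standard deviation. Background pixels that are
    exactly zero (masked-out crops) are ignored in the global stats."""
    imgs = np.asarray(images, dtype=float)
    if imgs.ndim == 3:
        imgs = imgs[None]
    n, h, w, _ = imgs.shape
    feats = []
    ys = np.linspace(0, h, grid + 1).astype(int)
    xs = np.linspace(0, w, grid + 1).astype(int)
    for img in imgs:
        valid = img.sum(axis=2) > 1e-6
        cells = []
        for i in range(grid):
            for j in range(grid):
                patch = img[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
                pv = valid[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
                cells.append(
                    patch[pv].mean(axis=0) if pv.any() else np.zeros(3)
                )
        g = img[valid] if valid.any() else np.zeros((1, 3))
        feats.append(np.concatenate(cells + [g.mean(axis=0), g.std(axis=0)]))
    # center and rescale: raw colour stats live in [0, 1], which starves
    # plain SGD at lr 1e-2 of gradient signal
    return (np.asarray(feats) - 0.4) * 5.0


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class HierarchicalClassifier:
    """Shared hidden layer + three parallel linear-softmax heads.

    ``backbone`` maps a batch of images to feature vectors; the trainable
    part is ``features -> ReLU(W_h) -> (head_1, head_2, head_3)`` with head
    widths equal to the taxonomy level sizes (coarse to fine).
    """

    def __init__(
        self,
        taxonomy: FoodTaxonomy,
        backbone=color_stat_features,
        hidden: int = 64,
        feature_dim: int | None = None,
        seed: int = 0,
        head_levels=LEVELS,
    ):
        self.taxonomy = taxonomy
        self.backbone = backbone
        self.head_levels = tuple(head_levels)
        sizes = dict(zip(LEVELS, taxonomy.level_sizes))
        self.head_sizes = tuple(sizes[lv] for lv in self.head_levels)
        if feature_dim is None:
            probe = backbone(np.zeros((1, 8, 8, 3)))
            feature_dim = probe.shape[1]
        rng = np.random.default_rng(seed)
        scale = np.sqrt(2.0 / feature_dim)
        self.W_h = rng.normal(0.0, scale, (feature_dim, hidden))
        self.b_h = np.zeros(hidden)
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / hidden), (hidden, c)) for c in self.head_sizes
        ]
        self.b = [np.zeros(c) for c in self.head_sizes]

    def _forward(self, feats: np.ndarray):
        pre = feats @ self.W_h + self.b_h
        hid = np.maximum(pre, 0.0)
        probs = [_softmax(hid @ W + b) for W, b in zip(self.W, self.b)]
        return hid, pre, probs

    def predict_proba(self, images: np.ndarray):
        """Per-level probability vectors, ordered like ``head_levels``."""
        feats = self.backbone(images)
        _, _, probs = self._forward(feats)
        return probs

    def parameters(self):
        return [self.W_h, self.b_h, *self.W, *self.b]

    def save(self, path) -> None:
        arrays = {"W_h": self.W_h, "b_h": self.b_h}
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            arrays[f"W_{i}"] = W
            arrays[f"b_{i}"] = b
        np.savez(path, **arrays)

    def load(self, path) -> None:
        data = np.load(path)
        self.W_h = data["W_h"]
        self.b_h = data["b_h"]
        self.W = [data[f"W_{i}"] for i in range(len(self.W))]
        self.b = [data[f"b_{i}"] for i in range(len(self.b))]


def build_model(
    taxonomy: FoodTaxonomy, backbone=color_stat_features, hidden: int = 64, seed: int = 0
) -> HierarchicalClassifier:
    """Joint model: shared backbone, three parallel heads sized to the
    taxonomy levels."""
    return HierarchicalClassifier(taxonomy, backbone, hidden=hidden, seed=seed)


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    """Defaults follow the published recipe: SGD, lr 1e-2, batch 32,
    20 epochs."""

    learning_rate: float = 1e-2
    batch_size: int = 32
    epochs: int = 20
    level_weights: tuple = (1.0, 1.0, 1.0)
    seed: int = 0
    augmentations: tuple = ()   # callables image -> image, applied in order


@dataclass
class TrainLog:
    loss: list = field(default_factory=list)
    accuracy: list = field(default_factory=list)  # per-epoch dict level -> acc


def _dataset_label_matrix(dataset, model: HierarchicalClassifier) -> np.ndarray:
    cols = {
        "hyper1": dataset.hyper1_idx,
        "hyper2": dataset.hyper2_idx,
        "fine": dataset.fine_idx,
    }
    y = np.stack([cols[lv] for lv in model.head_levels], axis=1)
    for j, size in enumerate(model.head_sizes):
        if (y[:, j] < 0).any() or (y[:, j] >= size).any():
            raise TaxonomyError(
                f"dataset contains labels outside the taxonomy at level "
                f"'{model.head_levels[j]}'"
            )
    return y


def joint_loss(probs, y, level_weights) -> float:
    """Weighted sum of per-level cross-entropies (mean over the batch)."""
    total = 0.0
    for j, (p, w) in enumerate(zip(probs, level_weights)):
        total += w * float(
            -np.log(np.maximum(p[np.arange(len(y)), y[:, j]], 1e-12)).mean()
        )
    return total


def train(
    model: HierarchicalClassifier, dataset, config: TrainConfig | None = None
) -> TrainLog:
    """Joint SGD over the summed per-level cross-entropies.

    ``dataset`` is any object with ``images`` and per-level index arrays
    (``fine_idx``, ``hyper2_idx``, ``hyper1_idx``) — e.g. the synthetic
    :class:`dietvision.scene.ClassificationSet`.
    """
    if config is None:
        config = TrainConfig()
    y = _dataset_label_matrix(dataset, model)
    images = dataset.images
    rng = np.random.default_rng(config.seed)
    log = TrainLog()
    n = len(images)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = images[idx]
            for aug in config.augmentations:
                batch = np.stack([aug(im) for im in batch])
            feats = model.backbone(batch)
            hid, pre, probs = model._forward(feats)
            yb = y[idx]
            epoch_loss += joint_loss(probs, yb, config.level_weights) * len(idx)

            b = len(idx)
            d_hid = np.zeros_like(hid)
            for j, (p, w) in enumerate(zip(probs, config.level_weights)):
                if w == 0:
                    continue
                dlogits = p.copy()
                dlogits[np.arange(b), yb[:, j]] -= 1.0
                dlogits *= w / b
                model.W[j] -= config.learning_rate * (hid.T @ dlogits)
                model.b[j] -= config.learning_rate * dlogits.sum(axis=0)
                d_hid += dlogits @ model.W[j].T
            d_pre = d_hid * (pre > 0)
            model.W_h -= config.learning_rate * (feats.T @ d_pre)
            model.b_h -= config.learning_rate * d_pre.sum(axis=0)
        log.loss.append(epoch_loss / n)
        probs = model.predict_proba(images)
        log.accuracy.append(
            {
                lv: float((np.argmax(p, axis=1) == y[:, j]).mean())
                for j, (lv, p) in enumerate(zip(model.head_levels, probs))
            }
        )
    return log


# ---------------------------------------------------------------------------
# inference


@dataclass(frozen=True)
class RecognitionScores:
    """Per-level probabilities plus the weighted-inference outcome."""

    level_probs: dict          # level name -> probability vector
    level_argmax: dict         # level name -> (index, raw max prob)
    chosen_level: str
    chosen_index: int
    chosen_label: str | None
    chosen_confidence: float   # weighted confidence of the chosen tag


def weighted_inference(
    per_level_probs,
    level_weights=(0.4, 0.5, 1.0),
    fallback_threshold: float = 0.5,
    taxonomy: FoodTaxonomy | None = None,
) -> RecognitionScores:
    """Pick the reported tag among the three level predictions.

    The confidence of level ``l`` is ``weight_l * max(probs_l)``; the tag
    with the highest confidence wins, ties going to the finer level. When
    the fine-grained raw max-probability falls below ``fallback_threshold``
    the fine level is excluded first (hyper-category fallback for unknown
    foods). Comparing *raw* max-probability against the threshold keeps the
    rule invariant to rescaling all weights.
    """
    weights = np.asarray(level_weights, dtype=float)
    if (weights < 0).any() or weights.sum() == 0:
        raise ValueError("level weights must be >= 0 and not all zero")
    probs = {lv: np.asarray(p, dtype=float) for lv, p in zip(LEVELS, per_level_probs)}
    for lv, p in probs.items():
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"{lv} probabilities do not sum to 1")
    argmax = {lv: (int(np.argmax(p)), float(p.max())) for lv, p in probs.items()}
    weighted = {
        lv: weights[i] * argmax[lv][1] for i, lv in enumerate(LEVELS)
    }
    candidates = list(LEVELS)
    if argmax["fine"][1] < fallback_threshold:
        candidates.remove("fine")
    # ties break toward the finer level: scan fine -> coarse
    best_level = None
    best_conf = -np.inf
    for lv in reversed(candidates):
        if weighted[lv] > best_conf + 1e-15:
            best_level = lv
            best_conf = weighted[lv]
    idx = argmax[best_level][0]
    label = taxonomy.name_at(best_level, idx) if taxonomy is not None else None
    return RecognitionScores(
        level_probs=probs,
        level_argmax=argmax,
        chosen_level=best_level,
        chosen_index=idx,
        chosen_label=label,
        chosen_confidence=float(weighted[best_level]),
    )


def center_crop(image: np.ndarray, fraction: float = 1.0) -> np.ndarray:
    if fraction >= 1.0:
        return image
    h, w = image.shape[:2]
    ch, cw = max(1, int(h * fraction)), max(1, int(w * fraction))
    top, left = (h - ch) // 2, (w - cw) // 2
    return image[top : top + ch, left : left + cw]


def topk_accuracy(model: HierarchicalClassifier, dataset, k: int = 3, crop_fraction: float = 1.0):
    """Per-level top-1 and top-k hit rates on one center crop per image."""
    if k < 1:
        raise ValueError("k must be >= 1")
    y = _dataset_label_matrix(dataset, model)
    images = np.stack([center_crop(im, crop_fraction) for im in dataset.images])
    probs = model.predict_proba(images)
    table = {}
    for j, lv in enumerate(model.head_levels):
        p = probs[j]
        order = np.argsort(-p, axis=1)
        top1 = (order[:, 0] == y[:, j]).mean()
        kk = min(k, p.shape[1])
        topk = (order[:, :kk] == y[:, j, None]).any(axis=1).mean()
        table[lv] = {"top1": float(top1), f"top{k}": float(topk)}
    return table


def compare_joint_vs_independent(
    taxonomy: FoodTaxonomy, dataset, config: TrainConfig | None = None, k: int = 3
):
    """Train the joint three-head model and three independent single-head
    models on identical data; report both per-level accuracy tables."""
    if config is None:
        config = TrainConfig()
    joint = build_model(taxonomy, seed=config.seed)
    train(joint, dataset, config)
    joint_table = topk_accuracy(joint, dataset, k)
    indep_table = {}
    for lv in LEVELS:
        m = HierarchicalClassifier(taxonomy, seed=config.seed, head_levels=(lv,))
        train(m, dataset, config)
        indep_table[lv] = topk_accuracy(m, dataset, k)[lv]
    return {"joint": joint_table, "independent": indep_table}


def export_prediction_json(scores: RecognitionScores, path) -> None:
    payload = {
        "chosen": {
            "level": scores.chosen_level,
            "index": scores.chosen_index,
            "label": scores.chosen_label,
            "confidence": scores.chosen_confidence,
        },
        "per_level": {
            lv: {"probs": p.tolist(), "argmax": scores.level_argmax[lv][0]}
            for lv, p in scores.level_probs.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
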