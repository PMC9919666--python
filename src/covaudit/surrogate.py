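"""Random-forest surrogate distillation and decision-path feature tracing.

A random forest is trained on the *black box's* outputs, not ground truth,
so the surrogate approximates the model under validation. Because the black
box is deterministic, duplicate inputs always carry identical labels and the
training problem is noiseless.

Forest fitting delegates to scikit-learn, but fitted trees are immediately
converted into this module's own :class:`DecisionNode` structure. Tracing,
serialization and all downstream coverage computations run on that structure
only, so they are independent of the training backend.

Unlike saliency scores, a decision path is unambiguous: the features a
sample *uses* are exactly those tested at the internal nodes on its
root-to-leaf path in each tree.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .datagen import DEFOLIATED, HEALTHY, Image

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurrogateConfig:
    """Forest hyperparameters.

    20 trees of maximum depth 20 are the reference configuration for this
    validation method; ``max_features`` and ``bootstrap`` follow the usual
    classifier defaults (sqrt feature subsampling, bootstrap resampling)
    and are exposed because they shape which features the forest can use.
    """

    n_trees: int = 20
    max_depth: int = 20
    seed: int = 0
    max_features: str | int | float | None = "sqrt"
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class DecisionNode:
    """A binary tree node: internal (feature test) or leaf (class probs).

    Internal nodes route a sample left when ``x[feature] <= threshold``.
    Leaf ``probs`` is ``(p_healthy, p_defoliated)``.
    """

    feature: int | None = None
    threshold: float | None = None
    left: "DecisionNode | None" = None
    right: "DecisionNode | None" = None
    probs: tuple[float, float] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.probs is not None

    def __post_init__(self) -> None:
        if self.probs is None:
            if self.feature is None or self.left is None or self.right is None:
                raise ValueError("internal node needs feature, threshold and two children")


@dataclass
class SurrogateForest:
    """A distilled forest over flattened pixel features.

    ``n_features = H*W``; feature index = row*W + col (row-major, 0-based).
    """

    trees: list[DecisionNode]
    n_features: int
    height: int
    width: int
    config: SurrogateConfig = field(default_factory=SurrogateConfig)
    classes: tuple[int, int] = (HEALTHY, DEFOLIATED)

    def all_node_features(self) -> set[int]:
        """Pixel features appearing at any internal node of any tree."""
        feats: set[int] = set()
        for root in self.trees:
            stack = [root]
            while stack:
                node = stack.pop()
                if not node.is_leaf:
                    feats.add(node.feature)
                    stack.append(node.left)
                    stack.append(node.right)
        return feats


@dataclass(frozen=True)
class FeatureUsage:
    """Features tested on one sample's realized decision paths.

    ``used`` is the union over trees of the feature indices tested on the
    root-to-leaf path taken by the sample; ``node_visits`` counts every
    internal-node test along those paths (trials, in coupon-collector terms),
    so ``len(used) <= node_visits <= n_trees * max_depth``.
    """

    sample_id: str
    used: frozenset[int]
    node_visits: int


def _check_shape(forest: SurrogateForest, image: Image) -> None:
    if image.pixels.shape != (forest.height, forest.width):
        raise ValueError(
            f"image shape {image.pixels.shape} does not match forest "
            f"({forest.height}, {forest.width})"
        )


def _convert_sklearn_tree(tree, classes_: np.ndarray) -> DecisionNode:
    """Convert a fitted sklearn tree into a DecisionNode tree.

    Leaf probabilities are re-indexed onto (healthy, defoliated) regardless
    of which classes sklearn saw.
    """
    t = tree.tree_

    def build(i: int) -> DecisionNode:
        if t.children_left[i] == -1:  # leaf
            counts = t.value[i][0]
            total = counts.sum()
            p = counts / total if total > 0 else np.full_like(counts, 0.5)
            probs = [0.0, 0.0]
            for cls, pi in zip(classes_, p):
                probs[int(cls)] = float(pi)
            return DecisionNode(probs=(probs[0], probs[1]))
        return DecisionNode(
            feature=int(t.feature[i]),
            threshold=float(t.threshold[i]),
            left=build(t.children_left[i]),
            right=build(t.children_right[i]),
        )

    return build(0)


def train_surrogate(
    images: Sequence[Image],
    blackbox_labels: Sequence[int],
    config: SurrogateConfig = SurrogateConfig(),
) -> SurrogateForest:
    """Distill the black box into a random forest.

    ``blackbox_labels`` must be the black box's outputs on ``images`` —
    training against the model under validation, not against ground truth,
    is what makes the forest a surrogate.

    If the black box predicted only one class, a degenerate forest of
    single-leaf trees is returned with a warning: there is nothing to split
    on, and every tree votes that class.
    """
    if len(images) != len(blackbox_labels):
        raise ValueError("images and labels must be aligned")
    if len(images) < 2:
        raise ValueError("need at least 2 training samples")
    H, W = images[0].pixels.shape
    X = np.stack([img.features() for img in images])
    y = np.asarray(blackbox_labels, dtype=int)

    if len(np.unique(y)) < 2:
        only = int(y[0])
        logger.warning(
            "black box predicted a single class (%d); returning a degenerate "
            "all-leaf forest",
            only,
        )
        probs = (1.0, 0.0) if only == HEALTHY else (0.0, 1.0)
        trees = [DecisionNode(probs=probs) for _ in range(config.n_trees)]
        return SurrogateForest(trees=trees, n_features=H * W, height=H, width=W, config=config)

    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features=config.max_features,
        bootstrap=config.bootstrap,
        random_state=config.seed,
    )
    clf.fit(X, y)
    trees = [_convert_sklearn_tree(est, clf.classes_) for est in clf.estimators_]
    return SurrogateForest(trees=trees, n_features=H * W, height=H, width=W, config=config)


def classify(forest: SurrogateForest, image: Image) -> int:
    """Aggregate per-tree leaf probabilities and return the majority label.

    Each tree contributes its leaf's class-probability vector; vectors are
    averaged across trees and the argmax taken. An exact tie goes to
    *defoliated* — with a binary alert, a conservative tie-break favors
    sending the farmer to look.
    """
    _check_shape(forest, image)
    x = image.features()
    p = np.zeros(2)
    for root in forest.trees:
        node = root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        p += node.probs
    p /= len(forest.trees)
    return DEFOLIATED if p[DEFOLIATED] >= p[HEALTHY] else HEALTHY


def fidelity(
    forest: SurrogateForest,
    images: Sequence[Image],
    blackbox_labels: Sequence[int],
) -> float:
    """Fraction of images where the surrogate reproduces the black-box label."""
    if len(images) == 0:
        raise ValueError("fidelity of an empty set is undefined")
    if len(images) != len(blackbox_labels):
        raise ValueError("images and labels must be aligned")
    hits = sum(
        classify(forest, img) == int(lab) for img, lab in zip(images, blackbox_labels)
    )
    return hits / len(images)


def trace_used_features(forest: SurrogateForest, image: Image) -> FeatureUsage:
    """Record which pixel features the forest tests while classifying ``image``.

    Walks the realized root-to-leaf path in every tree; ``used`` is the union
    of tested feature indices and ``node_visits`` the total number of
    internal-node tests. A feature present elsewhere in a tree but not on
    this sample's path is *not* used (forest-wide presence is
    ``SurrogateForest.all_node_features``).
    """
    _check_shape(forest, image)
    x = image.features()
    used: set[int] = set()
    visits = 0
    for root in forest.trees:
        node = root
        while not node.is_leaf:
            used.add(node.feature)
            visits += 1
            node = node.left if x[node.feature] <= node.threshold else node.right
    return FeatureUsage(sample_id=image.id, used=frozenset(used), node_visits=visits)


def trace_all(forest: SurrogateForest, images: Sequence[Image]) -> list[FeatureUsage]:
    """Trace every image; order preserved."""
    return [trace_used_features(forest, img) for img in images]


def feature_visit_counts(
    forest: SurrogateForest, images: Sequence[Image]
) -> np.ndarray:
    """Per-feature count of node visits across all samples' decision paths.

    This weights each split node by its sample traffic, which is how
    spatial bias in the black box shows up in the surrogate.
    """
    counts = np.zeros(forest.n_features, dtype=np.int64)
    for img in images:
        _check_shape(forest, img)
        x = img.features()
        for root in forest.trees:
            node = root
            while not node.is_leaf:
                counts[node.feature] += 1
                node = node.left if x[node.feature] <= node.threshold else node.right
    return counts


# ---------------------------------------------------------------------------
# JSON serialization (round-trip exact)
# ---------------------------------------------------------------------------


def _node_to_dict(node: DecisionNode) -> dict:
    if node.is_leaf:
        return {"probs": list(node.probs)}
    return {
        "feature": node.feature,
        "threshold": node.threshold,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict) -> DecisionNode:
    if "probs" in d:
        return DecisionNode(probs=tuple(d["probs"]))
    return DecisionNode(
        feature=int(d["feature"]),
        threshold=float(d["threshold"]),
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def forest_to_json(forest: SurrogateForest, path: str | Path) -> None:
    doc = {
        "n_features": forest.n_features,
        "height": forest.height,
        "width": forest.width,
        "classes": list(forest.classes),
        "config": {
            "n_trees": forest.config.n_trees,
            "max_depth": forest.config.max_depth,
            "seed": forest.config.seed,
            "max_features": forest.config.max_features,
            "bootstrap": forest.config.bootstrap,
        },
        "trees": [_node_to_dict(t) for t in forest.trees],
    }
    Path(path).write_text(json.dumps(doc))


def forest_from_json(path: str | Path) -> SurrogateForest:
    doc = json.loads(Path(path).read_text())
    cfg = SurrogateConfig(**doc["config"])
    return SurrogateForest(
        trees=[_node_from_dict(t) for t in doc["trees"]],
        n_features=int(doc["n_features"]),
        height=int(doc["height"]),
        width=int(doc["width"]),
        config=cfg,
        classes=tuple(doc["classes"]),
    )
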