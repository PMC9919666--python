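"""Shared fixtures: the pinned synthetic benchmark and a spatially biased
variant, plus small hand-built forests with traceable structure."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from covaudit import (
    DecisionNode,
    GenConfig,
    SurrogateConfig,
    SurrogateForest,
    generate_field_images,
    make_blackbox,
    trace_all,
    train_surrogate,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def _build_scenario(gen_cfg: GenConfig, blackbox_kind: str, n_train: int):
    dataset = generate_field_images(gen_cfg)
    images = [img for img, _, _ in dataset]
    masks = {img.id: mask for img, mask, _ in dataset}
    if blackbox_kind == "fraction_oracle":
        bb = make_blackbox("fraction_oracle", {"masks": masks})
    else:
        region = np.zeros((gen_cfg.H, gen_cfg.W), dtype=bool)
        region[:, : gen_cfg.W // 2] = True
        bb = make_blackbox("region_restricted", {"masks": masks, "region": region})
    labels = bb.label_all(images)
    forest = train_surrogate(images[:n_train], labels[:n_train], SurrogateConfig(seed=0))
    test_images = images[n_train:]
    usages = trace_all(forest, test_images)
    return SimpleNamespace(
        gen_cfg=gen_cfg,
        images=images,
        masks=masks,
        blackbox=bb,
        labels=labels,
        train_images=images[:n_train],
        train_labels=labels[:n_train],
        test_images=test_images,
        test_labels=labels[n_train:],
        forest=forest,
        usages=usages,
        usage_map={u.sample_id: u for u in usages},
    )


@pytest.fixture(scope="session")
def benchmark():
    """Pinned synthetic benchmark: 2,000 16x16 tiles, defoliation-fraction
    oracle black box, 1,400/600 train/test split, reference forest config."""
    cfg = GenConfig(n_images=2000, H=16, W=16, blob_radius_range=(2, 5), seed=0)
    return _build_scenario(cfg, "fraction_oracle", n_train=1400)


@pytest.fixture(scope="session")
def biased():
    """Spatial-bias scenario: defoliation confined to the left half of every
    tile and a black box that only looks at the left half."""
    cfg = GenConfig(
        n_images=2000,
        H=16,
        W=16,
        bias_mode="half_left",
        blob_radius_range=(2, 5),
        seed=7,
    )
    return _build_scenario(cfg, "region_restricted", n_train=1400)


@pytest.fixture
def two_tree_forest():
    """Hand-built 2-tree forest on 4x4 images (16 features).

    For an all-bright image (every pixel > 0.5): tree A's path tests
    features {3, 7}, tree B's path tests {7, 11} -> used = {3, 7, 11},
    node_visits = 4.
    """
    leaf_h = lambda: DecisionNode(probs=(1.0, 0.0))
    leaf_d = lambda: DecisionNode(probs=(0.0, 1.0))
    tree_a = DecisionNode(
        feature=3,
        threshold=0.5,
        left=leaf_h(),
        right=DecisionNode(feature=7, threshold=0.5, left=leaf_h(), right=leaf_d()),
    )
    tree_b = DecisionNode(
        feature=7,
        threshold=0.5,
        left=leaf_d(),
        right=DecisionNode(feature=11, threshold=0.5, left=leaf_d(), right=leaf_h()),
    )
    return SurrogateForest(
        trees=[tree_a, tree_b],
        n_features=16,
        height=4,
        width=4,
        config=SurrogateConfig(n_trees=2, max_depth=2, seed=0),
    )
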