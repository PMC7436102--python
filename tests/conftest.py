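import numpy as np
import pytest

from dietvision.pipeline import default_nutrient_table, default_taxonomy
from dietvision.recognition import TrainConfig, build_model, train
from dietvision.scene import (
    FoodSolid,
    SceneSpec,
    make_classification_set,
    make_scene,
)


def rotation_angle_deg(Ra, Rb):
    c = (np.trace(Ra @ Rb.T) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


GOLDEN_SOLIDS = (
    FoodSolid(
        "spherical_cap", {"sphere_radius": 60.0, "height": 30.0},
        (-110.0, 20.0), 1, "fried_rice",
    ),
    FoodSolid(
        "half_ellipsoid", {"semi_x": 40.0, "semi_y": 34.0, "semi_z": 26.0},
        (95.0, 55.0), 6, "grilled_salmon",
    ),
)


@pytest.fixture(scope="session")
def golden_scene():
    """Fixed two-item reference scene used across modules."""
    spec = SceneSpec(solids=GOLDEN_SOLIDS, card_angle_deg=25.0)
    return make_scene(spec, seed=42)


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def nutrient_table():
    return default_nutrient_table()


@pytest.fixture(scope="session")
def trained_model(taxonomy):
    model = build_model(taxonomy, seed=0)
    dataset = make_classification_set(taxonomy, n_per_class=48, seed=0)
    train(model, dataset, TrainConfig(seed=0))
    return model
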