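"""Shared fixtures: small synthetic scenes and derived products.

Session-scoped so the scene/segmentation cost is paid once per run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from medusahead_obia.features import derive_layers, segmentation_layers
from medusahead_obia.objects import attach_training, build_object_table
from medusahead_obia.scene import default_scene_config, generate_scene
from medusahead_obia.segmentation import multiresolution_segment
from medusahead_obia.survey import (
    designate_sample_sets,
    simulate_field_survey,
    survey_reference_candidates,
)

SCENE_SEED = 42


@pytest.fixture(scope="session")
def scene():
    """A 48 m x 48 m realistic scene with derived layers."""
    cfg = default_scene_config(extent_m=(48.0, 48.0), preset="realistic", seed=SCENE_SEED)
    stack, truth = generate_scene(cfg)
    derive_layers(stack)
    return stack, truth


@pytest.fixture(scope="session")
def samples(scene):
    """Training/test reference samples designated from walkabout candidates."""
    _, truth = scene
    cands = survey_reference_candidates(truth, n_random=4000, per_patch=12, seed=SCENE_SEED + 1)
    counts = {
        "medusahead": 12,
        "ryegrass_brome": 8,
        "vetch": 8,
        "clover_brome": 10,
        "wild_oat": 8,
        "barbed_goatgrass": 6,
        "canarygrass": 6,
    }
    training, test = designate_sample_sets(
        cands, training_counts=counts, test_strata=(15, 15, 15), seed=SCENE_SEED + 2
    )
    return training, test


@pytest.fixture(scope="session")
def fine_level(scene):
    stack, _ = scene
    return multiresolution_segment(segmentation_layers(stack), 10.0)


@pytest.fixture(scope="session")
def object_table(scene, fine_level):
    stack, _ = scene
    return build_object_table(fine_level, stack)


@pytest.fixture(scope="session")
def training_objects(scene, samples, fine_level, object_table):
    stack, _ = scene
    training, _ = samples
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return attach_training(object_table, training, fine_level, stack)


@pytest.fixture(scope="session")
def surveyed_scene():
    """A wide scene with the full 20-transect survey laid out."""
    cfg = default_scene_config(extent_m=(96.0, 48.0), preset="realistic", seed=7)
    stack, truth = generate_scene(cfg)
    transects, segments, plots = simulate_field_survey(truth, seed=8)
    return stack, truth, transects, segments, plots


def assert_valid_partition(level):
    """Every non-masked pixel in exactly one object; every object 4-connected."""
    from scipy import ndimage

    lab = level.label_raster
    assert lab.max() == level.n_objects - 1
    ids = np.unique(lab[lab >= 0])
    assert len(ids) == level.n_objects
    # connectivity, checked inside each object's bounding box
    for oid, sl in enumerate(ndimage.find_objects(lab + 1)):
        assert sl is not None, f"object {oid} missing"
        assert ndimage.label(lab[sl] == oid)[1] == 1, f"object {oid} disconnected"
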