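import numpy as np
import pytest
from hypothesis import settings

from cellflow import pipeline, report, synth

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return report.ExperimentConfig(seed=11)


@pytest.fixture(scope="session")
def trained_classifier(default_config):
    """One pixel classifier shared by segmentation tests, trained on
    labelled pixels sampled from a rendered scene."""
    scene = synth.shear_cohort_scene(270, rng_seed=default_config.seed)
    return pipeline.train_classifier_on_scene(scene, default_config)


def single_cell_scene(
    volume=60.0,
    centroid=(64.3, 63.7),
    orientation=0.9,
    noise=True,
    seed=5,
    division_time=None,
    loss_time=None,
    growth_rate=0.0,
    image_shape=(128, 128),
):
    """One-cell scene helper used across test modules."""
    cell = synth.CellSpec(
        centroid=centroid,
        orientation=orientation,
        growth_coeffs=(0.0, 0.0, growth_rate, volume),
        division_time=division_time,
        loss_time=loss_time,
    )
    kwargs = {} if noise else {"background_sd": 0.0, "foreground_sd": 0.0}
    return synth.SceneSpec(image_shape=image_shape, cells=[cell], rng_seed=seed, **kwargs)
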