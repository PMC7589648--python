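"""Shared fixtures: scenes, background models and small synthetic datasets.

Everything is generated programmatically with fixed seeds; session scope
keeps the slower artifacts (backgrounds, datasets) built once.
"""

import numpy as np
import pytest

import thermofall as tf
from thermofall import pipeline


@pytest.fixture(scope="session")
def clean_scene() -> tf.SceneConfig:
    """Noise-free scene for deterministic pipeline checks."""
    return tf.SceneConfig(noise_sigma_k=0.0, seed=3)


@pytest.fixture(scope="session")
def noisy_scene() -> tf.SceneConfig:
    """Scene at the sensor's mid-band noise level (0.2 K)."""
    return tf.SceneConfig(noise_sigma_k=0.2, seed=3)


@pytest.fixture(scope="session")
def clean_background(clean_scene) -> tf.BackgroundModel:
    return pipeline.background_from_scene(clean_scene, n_init=10, seed=5)


@pytest.fixture(scope="session")
def noisy_background(noisy_scene) -> tf.BackgroundModel:
    return pipeline.background_from_scene(noisy_scene, n_init=150, seed=5)


@pytest.fixture(scope="session")
def small_dataset(noisy_scene):
    """2 recordings per class, 2 synthetic subjects."""
    return tf.make_dataset(2, noisy_scene, seed=11, n_subjects=2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def blob_foreground(center=(12, 16), radius=2, value=3.0, shape=(24, 32)):
    """A square uniform warm patch on a zero foreground."""
    delta = np.zeros(shape)
    r, c = center
    delta[r - radius : r + radius + 1, c - radius : c + radius + 1] = value
    return tf.ForegroundFrame(delta=delta, source_index=0)
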