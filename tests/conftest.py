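"""Shared fixtures: synthetic scenes and the pooled MIX P2 dataset."""

from __future__ import annotations

import numpy as np
import pytest

from swallowsound import SceneSpec, detection_recall, generate_scene
from swallowsound.config import PipelineConfig
from swallowsound.pipeline import detect_and_label, featurize

N_SCENES = 10
SNR_DB = 20.0


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def scenes_20db():
    """Ten default scenes at 20 dB SNR (3 swallow + 9 distractors each)."""
    return [generate_scene(SceneSpec(seed=seed, snr_db=SNR_DB)) for seed in range(N_SCENES)]


@pytest.fixture(scope="session")
def mixp2_dataset(scenes_20db, default_config):
    """Detected, labelled and featurised events pooled over the ten scenes.

    Returns (features, labels, mean detection recall vs ground truth).
    """
    features, labels, recalls = [], [], []
    for scene in scenes_20db:
        events = detect_and_label(scene.recording, scene.annotations, default_config)
        features.append(featurize(scene.recording, events, default_config))
        labels.append([ev.label for ev in events])
        recalls.append(detection_recall(events, scene.ground_truth))
    return (
        np.vstack(features),
        np.concatenate(labels).astype(np.int64),
        float(np.mean(recalls)),
    )
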