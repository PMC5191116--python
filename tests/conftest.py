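"""Shared fixtures: small synthetic scenes and a trained classifier.

The trained-model fixture is session-scoped because IVM training (feature
extraction on a full training scene plus greedy import selection) is the
most expensive shared step; tests that need a classifier reuse it.
"""

from __future__ import annotations

import numpy as np
import pytest

from vitis3d.classifier import TrainingSet, train_ivm
from vitis3d.config import PipelineConfig
from vitis3d.features import extract_features
from vitis3d.preprocess import preprocess
from vitis3d.synthetic import SceneConfig, generate_scene

SMALL_SCENE = dict(n_bunches=3, leaf_count=12, stem_count=1,
                   row_length=0.75, bunch_spacing=0.25)


@pytest.fixture(scope="session")
def train_scene():
    """Preprocessed small training scene with carried ground-truth labels."""
    scene = generate_scene(SceneConfig(seed=101, **SMALL_SCENE))
    clean, _ = preprocess(scene.cloud)
    feats = extract_features(clean, scene.cameras)
    return scene, clean, feats


@pytest.fixture(scope="session")
def trained_model(train_scene):
    """IVM trained on ~600 points per class of the training scene."""
    scene, clean, feats = train_scene
    rng = np.random.default_rng(42)
    rows = []
    for cls in (0, 1):
        idx = np.flatnonzero((clean.labels == cls) & feats.valid)
        rows.append(rng.choice(idx, size=min(600, idx.size), replace=False))
    rows = np.concatenate(rows)
    train = TrainingSet(features=feats.values[rows], labels=clean.labels[rows])
    return train_ivm(train, seed=7)


@pytest.fixture(scope="session")
def eval_scene():
    """Fresh-seed small evaluation scene, preprocessed, with features."""
    scene = generate_scene(SceneConfig(seed=202, **SMALL_SCENE))
    clean, _ = preprocess(scene.cloud)
    feats = extract_features(clean, scene.cameras)
    return scene, clean, feats


@pytest.fixture()
def config():
    return PipelineConfig(seed=5)


def recall_precision(labels: np.ndarray, truth: np.ndarray):
    tp = int(((labels == 1) & (truth == 1)).sum())
    fp = int(((labels == 1) & (truth == 0)).sum())
    fn = int(((labels == 0) & (truth == 1)).sum())
    return tp / max(tp + fn, 1), tp / max(tp + fp, 1)
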