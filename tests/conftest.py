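"""Shared fixtures: synthetic datasets and trained tiny-scale models.

The desk-scale study conditions used across the suite: exams with
planted label-dependent signal at 48 px base resolution, preprocessed
to S=8 slices at R=32, split 200/150/100 (train/validation/test), and
the tiny model configuration (D=32, E=32, one attention layer).
Training-heavy fixtures are session-scoped so each model is fitted once.
"""

from __future__ import annotations

import numpy as np
import pytest

from kneemil.model import ModelConfig
from kneemil.preprocess import PreprocessConfig, RawStudy, preprocess_dataset
from kneemil.synthetic import SynthConfig, generate_dataset
from kneemil.training import ExamArrays, Splits, TrainConfig, train_one

DATA_SEED = 7
TINY_PP = PreprocessConfig(S=8, R=32)


def make_arrays(n: int, offset: int, seed: int = DATA_SEED,
                base_resolution: int = 48) -> ExamArrays:
    dataset = generate_dataset(
        SynthConfig(n_exams=n, seed=seed, base_resolution=base_resolution),
        id_offset=offset)
    studies = [RawStudy(e.exam_id, e.views, e.labels) for e in dataset.exams]
    exams, _ = preprocess_dataset(studies, TINY_PP)
    return ExamArrays.from_exams(exams)


@pytest.fixture(scope="session")
def tiny_splits() -> Splits:
    return Splits(train=make_arrays(200, 0),
                  validation=make_arrays(150, 200),
                  test=make_arrays(100, 350))


@pytest.fixture(scope="session")
def small_splits() -> Splits:
    """A smaller split for fast mechanical tests (not learning checks)."""
    return Splits(train=make_arrays(48, 600),
                  validation=make_arrays(32, 648),
                  test=make_arrays(32, 680))


@pytest.fixture(scope="session")
def tiny_train_config() -> TrainConfig:
    return TrainConfig.tiny()


@pytest.fixture(scope="session")
def tiny_model_config() -> ModelConfig:
    return ModelConfig.tiny()


@pytest.fixture(scope="session")
def trained_multiscale(tiny_splits, tiny_model_config, tiny_train_config):
    """Multi-scale attention models trained on planted-signal data,
    one per protocol seed."""
    return {seed: train_one(tiny_splits, tiny_model_config,
                            tiny_train_config, seed)
            for seed in tiny_train_config.seeds}


@pytest.fixture(scope="session")
def trained_permuted(tiny_splits, tiny_model_config, tiny_train_config):
    """Same conditions but with training labels randomly permuted,
    destroying the image-label association."""
    rng = np.random.default_rng(0)
    shuffled = ExamArrays(
        X=tiny_splits.train.X,
        y=tiny_splits.train.y[rng.permutation(tiny_splits.train.n)],
        ids=tiny_splits.train.ids)
    null_splits = Splits(train=shuffled, validation=tiny_splits.validation,
                         test=tiny_splits.test)
    return {seed: train_one(null_splits, tiny_model_config,
                            tiny_train_config, seed)
            for seed in tiny_train_config.seeds}
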