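"""Shared fixtures.

The expensive piece — training the full default architecture on the 2,000
synthetic length-1000 reads — runs once per session and is shared by the
acceptance criteria that need a trained model.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from hostdeplete.calibration import calibrate_thresholds, classify, select_threshold
from hostdeplete.model import ModelConfig, build_model
from hostdeplete.sequence_io import encode_batch
from hostdeplete.synthetic_data import ReadSetSpec, generate_read_set
from hostdeplete.training import LabeledDataset, TrainingConfig, train

TRAIN_SEED = 11
MODEL_SEED = 5


@pytest.fixture
def tiny_config():
    """A config small enough for exhaustive/numerical checks."""
    return ModelConfig(
        num_conv_layers=2,
        filters_per_layer=3,
        kernel_length=3,
        pool_length=2,
        min_input_length=4,
    )


@pytest.fixture
def toy_model(tiny_config):
    return build_model(tiny_config, seed=3)


@pytest.fixture(scope="session")
def synth_split():
    """2,000 fixed-length synthetic reads with strong CG suppression contrast."""
    spec = ReadSetSpec(
        n_reads=2000,
        host_fraction=0.5,
        length_median=1000,
        length_sigma=0.0,
        min_length=1000,
        max_length=1000,
        seed=TRAIN_SEED,
    )
    reads, labels = generate_read_set(spec)
    pairs = [(r.bases, l) for r, l in zip(reads, labels)]
    return {
        "train": LabeledDataset(pairs[:1200]),
        "val": LabeledDataset(pairs[1200:1600]),
        "test": pairs[1600:],
    }


@pytest.fixture(scope="session")
def trained_model(synth_split):
    """Full default architecture trained on the synthetic split (<= 30 epochs).

    Mixed-length crop exposure (100/300/1000 bp) mirrors the multi-length
    training scheme and markedly improves generalization at this scale.
    """
    from hostdeplete.training import make_length_variants

    augmented = make_length_variants(synth_split["train"], (100, 300, 1000), seed=0)
    model = build_model(ModelConfig(), seed=MODEL_SEED)
    config = TrainingConfig(
        max_epochs=8,
        patience=30,
        seed=MODEL_SEED,
        batch_size=32,
        training_lengths=(100, 300, 1000),
    )
    model, history = train(model, augmented, synth_split["val"], config)
    return model, history


@pytest.fixture(scope="session")
def trained_predictions(trained_model, synth_split):
    """Calibrated threshold + test-split predictions of the trained model."""
    model, _ = trained_model
    table = calibrate_thresholds(model, synth_split["val"].reads, [1000])
    threshold = select_threshold(1000, table)
    bases = [b for b, _ in synth_split["test"]]
    truth = [l for _, l in synth_split["test"]]
    probs = model.forward(encode_batch(bases, 1000))
    preds = [classify(float(p), threshold) for p in probs]
    return {"bases": bases, "truth": truth, "preds": preds, "threshold": threshold}
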