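"""Training: BCE + L2 + input-gradient penalty, Adam, early stopping.

Each training batch is length-homogeneous (reads of one length form a
rectangular one-hot array); mixed-length exposure comes from
:func:`make_length_variants`, which crops every source read to each target
length at a seeded uniform position.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from hostdeplete.errors import ConfigError
from hostdeplete.model import ConvNet, _sigmoid
from hostdeplete.sequence_io import encode_batch

DEFAULT_TRAINING_LENGTHS = (100, 1000, 10000)


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    l2_lambda: float = 1e-5
    input_grad_lambda: float = 1e-4
    patience: int = 30
    training_lengths: Tuple[int, ...] = DEFAULT_TRAINING_LENGTHS
    batch_size: int = 64
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.patience < 0:
            raise ConfigError("patience must be >= 0")
        if self.input_grad_lambda < 0 or self.l2_lambda < 0:
            raise ConfigError("regularization coefficients must be >= 0")
        if not self.training_lengths:
            raise ConfigError("training_lengths must be non-empty")


@dataclass
class LabeledDataset:
    """Reads with binary labels and an optional provenance tag per read."""

    reads: List[Tuple[str, int]] = field(default_factory=list)
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = ["synthetic"] * len(self.reads)
        for bases, label in self.reads:
            if not bases:
                raise ConfigError("empty read in dataset")
            if label not in (0, 1):
                raise ConfigError(f"label must be 0/1, got {label}")

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def labels(self) -> List[int]:
        return [label for _, label in self.reads]


def make_length_variants(
    dataset: LabeledDataset,
    training_lengths: Sequence[int] = DEFAULT_TRAINING_LENGTHS,
    seed: int = 0,
) -> LabeledDataset:
    """One crop of each source read at every target length it can support.

    Crop positions are uniform and seeded; reads shorter than a target
    length contribute no variant at that length.
    """
    rng = np.random.default_rng(seed)
    reads: List[Tuple[str, int]] = []
    provenance: List[str] = []
    for (bases, label), tag in zip(dataset.reads, dataset.provenance):
        for target in sorted(training_lengths):
            if len(bases) < target:
                continue
            start = int(rng.integers(0, len(bases) - target + 1))
            reads.append((bases[start : start + target], label))
            provenance.append(tag)
    return LabeledDataset(reads, provenance)


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy, numerically stable."""
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    return float(np.mean(np.logaddexp(0.0, logits) - labels * logits))


def _l2_term(model: ConvNet) -> float:
    return float(
        sum(
            (p.astype(np.float64) ** 2).sum()
            for name, p in model.params.items()
            if not name.endswith("_b")
        )
    )


def loss(
    model: ConvNet,
    batch: np.ndarray,
    labels: Sequence[int],
    config: TrainingConfig = TrainingConfig(),
) -> float:
    """Mean BCE + l2_lambda * sum of squared weights + input-gradient penalty."""
    y = np.asarray(labels, dtype=np.float64)
    if batch.shape[0] != y.shape[0]:
        raise ValueError("batch and labels are misaligned")
    logits, cache = model.forward_cache(batch)
    value = bce_with_logits(logits, y)
    if config.l2_lambda > 0:
        value += config.l2_lambda * _l2_term(model)
    if config.input_grad_lambda > 0:
        g = model.input_gradient(cache)
        value += config.input_grad_lambda * float(
            (g.astype(np.float64) ** 2).sum() / batch.shape[0]
        )
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite loss: {value}")
    return value


def loss_and_grads(
    model: ConvNet, batch: np.ndarray, labels: Sequence[int], config: TrainingConfig
) -> Tuple[float, Dict[str, np.ndarray]]:
    y = np.asarray(labels, dtype=np.float32)
    logits, cache = model.forward_cache(batch)
    value = bce_with_logits(logits, y)
    dlogit = (_sigmoid(logits) - np.asarray(labels, dtype=logits.dtype)) / batch.shape[0]
    grads, _ = model.backward(cache, dlogit)
    if config.l2_lambda > 0:
        value += config.l2_lambda * _l2_term(model)
        for name, p in model.params.items():
            if not name.endswith("_b"):
                grads[name] = grads[name] + 2.0 * config.l2_lambda * p
    if config.input_grad_lambda > 0:
        penalty, pen_grads = model.input_grad_penalty(cache)
        value += config.input_grad_lambda * penalty
        for name in grads:
            grads[name] = grads[name] + config.input_grad_lambda * pen_grads[name]
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite loss: {value}")
    return value, grads


class AdamOptimizer:
    def __init__(self, params: Dict[str, np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads[k].astype(np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _group_by_length(dataset: LabeledDataset) -> Dict[int, List[int]]:
    groups: Dict[int, List[int]] = {}
    for idx, (bases, _) in enumerate(dataset.reads):
        groups.setdefault(len(bases), []).append(idx)
    return groups


def validation_loss(model: ConvNet, dataset: LabeledDataset, batch_size: int = 256) -> float:
    """Plain mean BCE over the whole validation set (no regularizers)."""
    total, n = 0.0, 0
    for length, indices in sorted(_group_by_length(dataset).items()):
        for start in range(0, len(indices), batch_size):
            chunk = indices[start : start + batch_size]
            batch = encode_batch([dataset.reads[i][0] for i in chunk], length)
            y = np.array([dataset.reads[i][1] for i in chunk], dtype=np.float64)
            logits = model.logits(batch)
            total += float(np.sum(np.logaddexp(0.0, logits) - y * logits))
            n += len(chunk)
    return total / n


def train(
    model: ConvNet,
    train_data: LabeledDataset,
    val_data: LabeledDataset,
    config: TrainingConfig = TrainingConfig(),
) -> Tuple[ConvNet, List[Dict[str, float]]]:
    """Adam training with patience-based early stopping.

    Stops once the validation loss has not improved for ``patience``
    consecutive epochs (or at ``max_epochs``) and restores the weights from
    the best validation epoch.  Returns the model and a per-epoch history of
    train/validation losses.
    """
    for name, data in (("training", train_data), ("validation", val_data)):
        if len(data) == 0:
            raise ConfigError(f"{name} dataset is empty")
        if len(set(data.labels)) < 2:
            raise ConfigError(f"{name} dataset must contain both classes")

    optimizer = AdamOptimizer(model.params, config.learning_rate)
    groups = _group_by_length(train_data)
    history: List[Dict[str, float]] = []
    best_val = np.inf
    best_params = model.copy_params()
    best_epoch = 0
    epochs_since_improve = 0

    for epoch in range(1, config.max_epochs + 1):
        rng = np.random.default_rng(config.seed + epoch)
        batches: List[Tuple[int, List[int]]] = []
        for length, indices in sorted(groups.items()):
            order = [indices[i] for i in rng.permutation(len(indices))]
            for start in range(0, len(order), config.batch_size):
                batches.append((length, order[start : start + config.batch_size]))
        rng.shuffle(batches)

        epoch_loss, seen = 0.0, 0
        for length, chunk in batches:
            batch = encode_batch([train_data.reads[i][0] for i in chunk], length)
            labels = [train_data.reads[i][1] for i in chunk]
            value, grads = loss_and_grads(model, batch, labels, config)
            optimizer.step(model.params, grads)
            epoch_loss += value * len(chunk)
            seen += len(chunk)

        val = validation_loss(model, val_data)
        history.append({"epoch": epoch, "train_loss": epoch_loss / seen, "val_loss": val})
        if val < best_val - 1e-12:
            best_val = val
            best_params = model.copy_params()
            best_epoch = epoch
            epochs_since_improve = 0
        else:
            epochs_since_improve += 1
        if epochs_since_improve >= config.patience and epochs_since_improve > 0:
            break

    model.load_params(best_params)
    return model, history


def write_history(history: Sequence[Dict[str, float]], path: os.PathLike | str) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=["epoch", "train_loss", "val_loss"])
        writer.writeheader()
        for row in history:
            writer.writerow(row)
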