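"""Length-dependent decision thresholds.

Host probabilities become binary labels through a table of per-length
thresholds; the entry whose calibration length is closest to the read length
is used, and calibration maximizes Youden's J (sensitivity + specificity - 1)
on validation data cropped to each calibration length.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from hostdeplete.errors import CalibrationError, ConfigError
from hostdeplete.sequence_io import encode_batch

DEFAULT_CALIBRATION_LENGTHS = (100, 150, 200, 300, 500, 1000, 5000, 10000)


@dataclass
class ThresholdTable:
    """Map from calibration length (bp) to decision probability."""

    entries: Dict[int, float] = field(
        default_factory=lambda: {length: 0.5 for length in DEFAULT_CALIBRATION_LENGTHS}
    )

    def __post_init__(self) -> None:
        if any(not 0.0 <= t <= 1.0 for t in self.entries.values()):
            raise ConfigError("thresholds must lie in [0, 1]")
        self.entries = dict(sorted(self.entries.items()))

    @classmethod
    def from_file(cls, path: os.PathLike | str) -> "ThresholdTable":
        entries: Dict[int, float] = {}
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("length"):
                    continue
                length, thresh = line.split("\t")
                entries[int(length)] = float(thresh)
        if not entries:
            raise ConfigError(f"no threshold entries in {path}")
        return cls(entries)

    def to_file(self, path: os.PathLike | str) -> None:
        with open(path, "w") as handle:
            handle.write("length\tthreshold\n")
            for length, thresh in self.entries.items():
                handle.write(f"{length}\t{thresh:.6g}\n")


def select_threshold(length: int, table: ThresholdTable) -> float:
    """Threshold of the calibration length closest to *length*.

    Ties break toward the smaller calibration length.
    """
    if not table.entries:
        raise ConfigError("empty threshold table")
    best = min(table.entries, key=lambda cal: (abs(cal - length), cal))
    return table.entries[best]


def classify(probability: float, threshold: float) -> int:
    """1 (host) iff probability is strictly above the threshold, else 0."""
    return 1 if probability > threshold else 0


def best_youden_threshold(
    probabilities: Sequence[float], labels: Sequence[int]
) -> Tuple[float, float]:
    """Exhaustive Youden's J scan over observed probabilities plus {0, 1}.

    Returns ``(threshold, J)`` with the smallest threshold among the optima.
    Requires both classes to be present.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("both classes are required to calibrate a threshold")
    grid = np.unique(np.concatenate([probs, [0.0, 1.0]]))
    best_thresh, best_j = 0.0, -np.inf
    for t in grid:
        pred = probs > t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_thresh, best_j = float(t), float(j)
    return best_thresh, best_j


def calibrate_thresholds(
    model,
    reads: Sequence[Tuple[str, int]],
    calibration_lengths: Sequence[int] = DEFAULT_CALIBRATION_LENGTHS,
    batch_size: int = 256,
) -> ThresholdTable:
    """Fit one threshold per calibration length on labeled validation reads.

    ``reads`` are ``(bases, label)`` pairs; for each calibration length the
    reads long enough are cropped (from the start) to that length, scored by
    the model, and the Youden-optimal threshold is recorded.  A length whose
    eligible slice contains a single class raises :class:`CalibrationError`.
    """
    entries: Dict[int, float] = {}
    for length in calibration_lengths:
        eligible = [(bases, label) for bases, label in reads if len(bases) >= length]
        if not eligible:
            raise CalibrationError(f"no validation reads of length >= {length}")
        probs: List[float] = []
        labels = [label for _, label in eligible]
        for start in range(0, len(eligible), batch_size):
            chunk = [bases for bases, _ in eligible[start : start + batch_size]]
            batch = encode_batch(chunk, length)
            probs.extend(model.forward(batch).tolist())
        try:
            thresh, _ = best_youden_threshold(probs, labels)
        except CalibrationError as exc:
            raise CalibrationError(f"calibration length {length}: {exc}") from exc
        entries[length] = thresh
    return ThresholdTable(entries)
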