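"""Inference-time preprocessing: length bins, batch plans, memory-bounded passes.

Reads are grouped by length into truncation bins (floor to a length
increment, capped at ``max_len``), batches hold at most
``batch_max_len / truncation_length`` reads, and passes bound the total
truncated bp held at once by ``lim``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import yaml

from hostdeplete.errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinningConfig:
    seq_cutoff: int = 5000
    inc1: int = 50
    inc2: int = 1000
    max_len: int = 6000
    lim: int = 1_200_000_000
    batch_max_len: int = 900_000

    def __post_init__(self) -> None:
        for name in ("seq_cutoff", "inc1", "inc2", "max_len", "lim", "batch_max_len"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.inc1 > self.inc2:
            raise ConfigError("inc1 must be <= inc2")
        if self.seq_cutoff > self.max_len:
            raise ConfigError("seq_cutoff must be <= max_len")
        if self.seq_cutoff % self.inc1 != 0:
            raise ConfigError("inc1 must divide seq_cutoff")

    @classmethod
    def from_file(cls, path: os.PathLike | str) -> "BinningConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {k: int(v) for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_file(self, path: os.PathLike | str) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__},
                handle,
                sort_keys=False,
            )


@dataclass
class LengthBin:
    truncation_length: int
    member_ids: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.member_ids)

    @property
    def total_bp(self) -> int:
        return self.truncation_length * len(self.member_ids)


def assign_bin(length: int, config: BinningConfig = BinningConfig()) -> int:
    """Map a read length to its truncation length.

    Lengths above ``max_len`` are capped there; above ``seq_cutoff`` the bin
    increment is ``inc2``, otherwise ``inc1``.  Lengths below ``inc1`` are
    rejected with :class:`ValueError` (the caller logs and skips).
    """
    if length < config.inc1:
        raise ValueError(f"read length {length} < minimum binnable length {config.inc1}")
    if length > config.max_len:
        return config.max_len
    if length > config.seq_cutoff:
        return (length // config.inc2) * config.inc2
    return (length // config.inc1) * config.inc1


def build_bins(
    reads: Iterable[Tuple[str, int]], config: BinningConfig = BinningConfig()
) -> List[LengthBin]:
    """Group ``(id, length)`` pairs into bins keyed by :func:`assign_bin`.

    Returns bins sorted by ascending truncation length; within-bin order is
    input order.  Too-short reads are logged and skipped.
    """
    bins: Dict[int, LengthBin] = {}
    rejected = 0
    for read_id, length in reads:
        try:
            trunc = assign_bin(length, config)
        except ValueError:
            rejected += 1
            logger.warning("rejecting read %r: length %d < %d", read_id, length, config.inc1)
            continue
        bins.setdefault(trunc, LengthBin(trunc)).member_ids.append(read_id)
    if rejected:
        logger.info("rejected %d read(s) shorter than %d bp", rejected, config.inc1)
    return [bins[k] for k in sorted(bins)]


def plan_batches(bin: LengthBin, config: BinningConfig = BinningConfig()) -> List[List[str]]:
    """Split a bin's members into batches of ``floor(batch_max_len / L)`` reads."""
    if bin.truncation_length > config.batch_max_len:
        raise ConfigError(
            f"truncation length {bin.truncation_length} exceeds batch_max_len {config.batch_max_len}"
        )
    n = config.batch_max_len // bin.truncation_length
    return [bin.member_ids[i : i + n] for i in range(0, len(bin.member_ids), n)]


def plan_passes(
    reads: Iterable[Tuple[str, int]], config: BinningConfig = BinningConfig()
) -> List[List[LengthBin]]:
    """Schedule bins into memory-bounded passes.

    Whole bins are packed greedily in ascending truncation-length order so
    that each pass holds at most ``lim`` truncated bp.  A single bin whose
    total bp alone exceeds ``lim`` is split across consecutive passes; any
    other bin that does not fit in the current pass starts the next one
    intact.
    """
    passes: List[List[LengthBin]] = []
    current: List[LengthBin] = []
    current_bp = 0

    def close() -> None:
        nonlocal current, current_bp
        if current:
            passes.append(current)
            current = []
            current_bp = 0

    for b in build_bins(reads, config):
        if b.truncation_length > config.lim:
            raise ConfigError(
                f"lim {config.lim} smaller than a single truncated read of {b.truncation_length} bp"
            )
        if b.total_bp <= config.lim:
            if current_bp + b.total_bp > config.lim:
                close()
            current.append(b)
            current_bp += b.total_bp
        else:
            close()
            per_pass = config.lim // b.truncation_length
            members = b.member_ids
            for start in range(0, len(members), per_pass):
                chunk = members[start : start + per_pass]
                close()
                current = [LengthBin(b.truncation_length, list(chunk))]
                current_bp = b.truncation_length * len(chunk)
    close()
    return passes
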