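"""FASTA/FASTQ I/O, one-hot encoding, and the tool's two output files.

Parsing and writing are delegated to :mod:`Bio.SeqIO`; this module owns the
record model (ids cut at the first whitespace, qualities kept verbatim) and
the numeric encoding used by the classifier.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from hostdeplete.errors import ConsistencyError, ParseError, UsageError

FORMATS = ("fasta", "fastq")

# byte value -> channel index; 4 marks ambiguity codes (zero row)
_BASE_INDEX = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
    _BASE_INDEX[_b + 32] = _i  # lowercase
_EYE5 = np.vstack([np.eye(4, dtype=np.float32), np.zeros((1, 4), dtype=np.float32)])


@dataclass
class Read:
    """One single-end sequence record."""

    id: str
    bases: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ParseError(f"read {self.id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.bases):
            raise ParseError(
                f"read {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.bases)}"
            )

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass
class ClassificationRecord:
    """Per-read decision: host probability, binary label, original length."""

    id: str
    probability: float
    label: int
    length: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability out of [0, 1]: {self.probability}")


def _check_format(fmt: str) -> str:
    if fmt not in FORMATS:
        raise UsageError(f"unknown sequence format {fmt!r}; expected one of {FORMATS}")
    return fmt


def read_sequences(path: os.PathLike | str, format: str) -> Iterator[Read]:
    """Yield every record of a FASTA/FASTQ file in file order.

    Ids are taken up to the first whitespace.  Malformed records raise
    :class:`ParseError` naming the (0-based) index of the offending record.
    """
    _check_format(format)
    parser = SeqIO.parse(str(path), format)
    index = 0
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise ParseError(f"malformed {format} record at index {index}: {exc}") from exc
        quality = None
        if format == "fastq":
            quality = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield Read(id=rec.id, bases=str(rec.seq), quality=quality)
        index += 1


def write_sequences(reads: Iterable[Read], format: str, path: os.PathLike | str) -> int:
    """Write reads to *path* in the given format; returns the record count."""
    _check_format(format)
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            rec = SeqRecord(Seq(read.bases), id=read.id, description="")
            if format == "fastq":
                if read.quality is None:
                    raise UsageError(f"read {read.id!r} has no quality but fastq output was requested")
                rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in read.quality]
            SeqIO.write(rec, handle, format)
            n += 1
    return n


def one_hot_encode(bases: str, target_length: int) -> np.ndarray:
    """Encode *bases* as a ``target_length x 4`` float32 matrix.

    A/C/G/T map to unit vectors, ambiguity codes to all-zero rows, and bases
    beyond ``target_length`` are discarded.  Case-insensitive.
    """
    if target_length < 1:
        raise ValueError(f"target_length must be >= 1, got {target_length}")
    if target_length > len(bases):
        raise ValueError(
            f"target_length {target_length} exceeds sequence length {len(bases)}"
        )
    raw = np.frombuffer(bases[:target_length].encode("ascii"), dtype=np.uint8)
    return _EYE5[_BASE_INDEX[raw]]


def encode_batch(sequences: Sequence[str], target_length: int) -> np.ndarray:
    """Encode equal-truncation sequences into an ``N x L x 4`` array."""
    out = np.empty((len(sequences), target_length, 4), dtype=np.float32)
    for i, seq in enumerate(sequences):
        out[i] = one_hot_encode(seq, target_length)
    return out


def write_predictions(records: Sequence[ClassificationRecord], path: os.PathLike | str) -> None:
    """Write the 3-column (id, label, length) TSV, one row per record."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f"{rec.id}\t{rec.label}\t{rec.length}\n")


def read_predictions(path: os.PathLike | str) -> Dict[str, int]:
    """Read a predictions TSV back into an id -> label mapping."""
    labels: Dict[str, int] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            rid, label, _length = line.rstrip("\n").split("\t")
            labels[rid] = int(label)
    return labels


def write_microbial_reads(
    reads: Iterable[Read],
    records: Mapping[str, ClassificationRecord] | Sequence[ClassificationRecord],
    format: str,
    path: os.PathLike | str,
) -> int:
    """Write exactly the reads labelled 0 (microbe), untruncated, to *path*.

    Returns the number of reads written.  Every record id must resolve to a
    read and vice versa, otherwise :class:`ConsistencyError` is raised.
    """
    _check_format(format)
    if not isinstance(records, Mapping):
        records = {rec.id: rec for rec in records}
    seen = set()

    def microbial() -> Iterator[Read]:
        for read in reads:
            try:
                rec = records[read.id]
            except KeyError:
                raise ConsistencyError(f"no classification record for read {read.id!r}")
            seen.add(read.id)
            if rec.label == 0:
                yield read

    n = write_sequences(microbial(), format, path)
    missing = set(records) - seen
    if missing:
        raise ConsistencyError(
            f"{len(missing)} record id(s) did not resolve to a read, e.g. {sorted(missing)[:3]}"
        )
    return n
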