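"""Synthetic Nanopore-like read generator.

Two first-order Markov composition profiles realize the compositional
contrast the classifier must learn: a host-like profile with a strongly
suppressed C->G transition (the vertebrate CpG-suppression phenomenon) and a
microbe-like profile without it.  Lengths follow a clipped log-normal and
optional per-base substitution/insertion/deletion noise mimics Nanopore
error.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from hostdeplete.errors import ConfigError
from hostdeplete.sequence_io import Read, write_sequences

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CompositionProfile:
    """First-order Markov chain over A/C/G/T."""

    transition_matrix: np.ndarray  # 4x4 row-stochastic
    initial_distribution: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = "profile"

    def __post_init__(self) -> None:
        t = np.asarray(self.transition_matrix, dtype=float)
        p0 = np.asarray(self.initial_distribution, dtype=float)
        object.__setattr__(self, "transition_matrix", t)
        object.__setattr__(self, "initial_distribution", p0)
        if t.shape != (4, 4) or p0.shape != (4,):
            raise ConfigError("profile must be a 4x4 matrix and a length-4 vector")
        if (t < 0).any() or (p0 < 0).any():
            raise ConfigError("probabilities must be non-negative")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("transition matrix rows must sum to 1")
        if not np.isclose(p0.sum(), 1.0, atol=1e-9):
            raise ConfigError("initial distribution must sum to 1")

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        return pi / pi.sum()

    def expected_cg_fraction(self) -> float:
        """Stationary probability of observing a 'CG' dimer."""
        pi = self.stationary_distribution()
        return float(pi[1] * self.transition_matrix[1, 2])


def host_profile(cg_transition: float = 0.01) -> CompositionProfile:
    """Uniform transitions except a suppressed C->G, mass redistributed in the C row."""
    t = np.full((4, 4), 0.25)
    t[1] = (1.0 - cg_transition) / 3.0
    t[1, 2] = cg_transition
    return CompositionProfile(t, name="host")


def microbe_profile() -> CompositionProfile:
    return CompositionProfile(np.full((4, 4), 0.25), name="microbe")


@dataclass(frozen=True)
class ReadSetSpec:
    n_reads: int = 1000
    host_fraction: float = 0.5
    length_median: float = 4000.0
    length_sigma: float = 1.0
    min_length: int = 100
    max_length: int = 30000
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.host_fraction <= 1.0:
            raise ConfigError("host_fraction must be in [0, 1]")
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.min_length < 50:
            raise ConfigError("min_length must be >= 50")
        if self.max_length < self.min_length:
            raise ConfigError("max_length must be >= min_length")


def _sample_chains(
    profile: CompositionProfile, lengths: Sequence[int], rng: np.random.Generator
) -> List[str]:
    """Vectorized-over-reads Markov sampling of many sequences at once."""
    lengths = np.asarray(lengths, dtype=int)
    if len(lengths) == 0:
        return []
    n, max_len = len(lengths), int(lengths.max())
    cum_t = np.cumsum(profile.transition_matrix, axis=1)
    cum_t[:, -1] = 1.0
    out = np.empty((n, max_len), dtype=np.uint8)
    state = np.searchsorted(np.cumsum(profile.initial_distribution), rng.random(n), side="right")
    state = np.minimum(state, 3)
    out[:, 0] = state
    u = rng.random((n, max_len))
    for pos in range(1, max_len):
        rows = cum_t[state]
        state = (u[:, pos][:, None] >= rows).sum(axis=1)
        out[:, pos] = state
    seqs = _BASE_ARR[out]
    return [seqs[i, : lengths[i]].tobytes().decode("ascii") for i in range(n)]


def sample_sequence(profile: CompositionProfile, length: int, seed: int) -> str:
    """One seeded sequence from the profile's Markov chain."""
    if length < 1:
        raise ConfigError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return _sample_chains(profile, [length], rng)[0]


def apply_noise(
    bases: str,
    rates: Tuple[float, float, float],
    seed: int | np.random.Generator,
) -> str:
    """Independent per-position substitution / insertion / deletion.

    Each position is deleted with probability ``del``; a surviving base is
    substituted (with a uniformly chosen *different* base) with probability
    ``sub``; one uniform base is inserted after each original position with
    probability ``ins``.  Expected length change is ``len * (ins - del)``.
    """
    sub, ins, dele = rates
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
    n = arr.size
    if dele > 0:
        keep = rng.random(n) >= dele
    else:
        keep = np.ones(n, dtype=bool)
    if sub > 0:
        hit = (rng.random(n) < sub) & keep
        # shift by 1..3 in base space => always a different base
        idx = np.searchsorted(_BASE_ARR, arr[hit])
        arr[hit] = _BASE_ARR[(idx + rng.integers(1, 4, size=hit.sum())) % 4]
    if ins > 0:
        ins_mask = rng.random(n) < ins
        ins_base = _BASE_ARR[rng.integers(0, 4, size=int(ins_mask.sum()))]
        pieces: List[np.ndarray] = []
        prev = 0
        for pos, b in zip(np.flatnonzero(ins_mask), ins_base):
            pieces.append(arr[prev : pos + 1][keep[prev : pos + 1]])
            pieces.append(np.array([b], dtype=np.uint8))
            prev = pos + 1
        pieces.append(arr[prev:][keep[prev:]])
        out = np.concatenate(pieces)
    else:
        out = arr[keep]
    return out.tobytes().decode("ascii")


def generate_read_set(
    spec: ReadSetSpec,
    host: Optional[CompositionProfile] = None,
    microbe: Optional[CompositionProfile] = None,
) -> Tuple[List[Read], List[int]]:
    """Labeled synthetic reads: exactly ``round(n * host_fraction)`` host reads.

    Returns the shuffled reads and their aligned 0/1 labels; everything is
    reproducible from ``(spec, profiles)``.
    """
    host = host or host_profile()
    microbe = microbe or microbe_profile()
    rng = np.random.default_rng(spec.seed)
    n_host = int(round(spec.n_reads * spec.host_fraction))
    lengths = np.exp(
        rng.normal(np.log(spec.length_median), spec.length_sigma, size=spec.n_reads)
    )
    lengths = np.clip(np.round(lengths).astype(int), spec.min_length, spec.max_length)
    host_seqs = _sample_chains(host, lengths[:n_host], rng)
    microbe_seqs = _sample_chains(microbe, lengths[n_host:], rng)
    rates = (spec.substitution_rate, spec.insertion_rate, spec.deletion_rate)
    reads: List[Read] = []
    labels: List[int] = []
    for i, seq in enumerate(host_seqs + microbe_seqs):
        label = 1 if i < n_host else 0
        if any(r > 0 for r in rates):
            seq = apply_noise(seq, rates, rng)
        reads.append(Read(id=f"read_{i:06d}", bases=seq, quality="I" * len(seq)))
        labels.append(label)
    order = rng.permutation(spec.n_reads)
    return [reads[i] for i in order], [labels[i] for i in order]


def write_read_set(
    reads: Sequence[Read],
    labels: Sequence[int],
    format: str,
    reads_path: os.PathLike | str,
    truth_path: os.PathLike | str,
) -> None:
    """Write reads plus the aligned (id, label) truth TSV."""
    write_sequences(reads, format, reads_path)
    with open(truth_path, "w") as handle:
        for read, label in zip(reads, labels):
            handle.write(f"{read.id}\t{label}\n")


def read_truth(path: os.PathLike | str) -> dict:
    truth = {}
    with open(path) as handle:
        for line in handle:
            if line.strip():
                rid, label = line.split("\t")
                truth[rid] = int(label)
    return truth
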