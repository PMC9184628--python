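"""Reference-based per-nucleotide contribution scores aggregated to k-mers.

Contributions follow the DeepLift rescale rule on the pre-sigmoid logit:
activation differences between the input and a reference are propagated back
through the network, multipliers through ReLU being delta-out over delta-in
(falling back to the input-side mask where the denominator vanishes).  The
reference set is a collection of seeded uniform permutations of the input's
own positions, so base composition is preserved; contributions are averaged
over references.  For linear + ReLU networks the rescale rule satisfies
completeness exactly: per-position scores sum to
``logit(input) - mean_ref logit(reference)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from hostdeplete.model import ConvNet, avgpool_backward, conv_backward_input
from hostdeplete.sequence_io import one_hot_encode

_RESCALE_EPS = 1e-7


@dataclass
class AttributionResult:
    """Signed per-position scores (positive toward host) and window sums."""

    read_id: str
    bases: str
    per_position: np.ndarray
    k: int = 15

    @property
    def kmer_scores(self) -> Dict[int, float]:
        """Window start -> exact sum of its k constituent position scores."""
        if len(self.per_position) < self.k:
            return {}
        sums = np.convolve(self.per_position, np.ones(self.k), mode="valid")
        return {i: float(sums[i]) for i in range(len(sums))}

    def window_profile(self, start: int) -> np.ndarray:
        return self.per_position[start : start + self.k]


def _deeplift_multiplier_pass(model: ConvNet, x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Per-position contribution scores of x against a batch of references.

    ``x`` is (L, 4); ``ref`` is (R, L, 4).  Returns (R, L) scores (channels
    summed) before averaging over references.
    """
    cfg = model.config
    r_count = ref.shape[0]
    xb = np.broadcast_to(x, ref.shape)
    logit_x, cache_x = model.forward_cache(np.ascontiguousarray(xb))
    logit_r, cache_r = model.forward_cache(ref)

    c = model.params["fc_w"].shape[0]
    ma = np.broadcast_to(
        (model.params["fc_w"] / cache_x["gap_length"]).astype(np.float32),
        (r_count, cache_x["gap_length"], c),
    )
    for i in reversed(range(cfg.num_conv_layers)):
        lay_x, lay_r = cache_x["layers"][i], cache_r["layers"][i]
        mr = avgpool_backward(np.ascontiguousarray(ma), cfg.pool_length, lay_x["in_length"])
        # reconstruct pre/post activations from the cached inputs
        zx = _conv_z(model, i, lay_x["a_in"])
        zr = _conv_z(model, i, lay_r["a_in"])
        dz = zx - zr
        dr = zx * lay_x["mask"] - zr * lay_r["mask"]
        ratio = np.where(np.abs(dz) > _RESCALE_EPS, dr / np.where(dz == 0, 1.0, dz), lay_x["mask"])
        mz = mr * ratio.astype(np.float32)
        ma = conv_backward_input(mz, model.params[f"conv{i}_W"], lay_x["a_in"].shape[2])
    contrib = ma * (xb - ref)
    return contrib.sum(axis=2)


def _conv_z(model: ConvNet, i: int, a_in: np.ndarray) -> np.ndarray:
    from hostdeplete.model import conv_forward

    return conv_forward(a_in, model.params[f"conv{i}_W"], model.params[f"conv{i}_b"])


def attribute(
    model: ConvNet,
    bases: str,
    n_references: int = 20,
    seed: int = 0,
    read_id: str = "read",
) -> AttributionResult:
    """DeepLift-style scores averaged over seeded permutation references."""
    length = len(bases)
    x = one_hot_encode(bases, length)
    rng = np.random.default_rng(seed)
    refs = np.empty((n_references, length, 4), dtype=np.float32)
    for r in range(n_references):
        refs[r] = x[rng.permutation(length)]
    scores = _deeplift_multiplier_pass(model, x, refs)
    return AttributionResult(
        read_id=read_id,
        bases=bases,
        per_position=scores.mean(axis=0).astype(np.float64),
        k=model.config.kernel_length,
    )


@dataclass
class KmerRanking:
    sequence: str
    mean_score: float
    count: int
    profile: np.ndarray


def top_kmers(
    results: Sequence[AttributionResult], m: int = 5
) -> Tuple[List[KmerRanking], List[KmerRanking]]:
    """Pool windows across reads by k-mer sequence and rank by mean score.

    Returns ``(top_m, bottom_m)`` — the most host-pushing and most
    microbe-pushing k-mers, each with its mean score, instance count, and
    mean per-position score profile.
    """
    if not results:
        raise ValueError("no attribution results to rank")
    pooled: Dict[str, List[Tuple[float, np.ndarray]]] = {}
    for res in results:
        for start, score in res.kmer_scores.items():
            kmer = res.bases[start : start + res.k]
            pooled.setdefault(kmer, []).append((score, res.window_profile(start)))
    rankings = [
        KmerRanking(
            sequence=kmer,
            mean_score=float(np.mean([s for s, _ in entries])),
            count=len(entries),
            profile=np.mean([p for _, p in entries], axis=0),
        )
        for kmer, entries in pooled.items()
    ]
    if len(rankings) < m:
        import warnings

        warnings.warn(f"only {len(rankings)} distinct k-mers available (requested {m})")
    rankings.sort(key=lambda r: (-r.mean_score, r.sequence))
    top = rankings[:m]
    bottom = sorted(rankings, key=lambda r: (r.mean_score, r.sequence))[:m]
    return top, bottom


def write_report(results: Sequence[AttributionResult], path: os.PathLike | str) -> None:
    """TSV of (read id, window start, k-mer sequence, score)."""
    with open(path, "w") as handle:
        handle.write("read_id\tstart\tkmer\tscore\n")
        for res in results:
            for start, score in sorted(res.kmer_scores.items()):
                kmer = res.bases[start : start + res.k]
                handle.write(f"{res.read_id}\t{start}\t{kmer}\t{score:.6g}\n")
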