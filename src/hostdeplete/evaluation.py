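"""Accuracy metrics, the naive CG baseline, CG strata, k-mer uniqueness.

Host is the positive class throughout: sensitivity is the fraction of true
host reads labeled host, specificity the fraction of true microbe reads
labeled microbe.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set

from hostdeplete.calibration import best_youden_threshold
from hostdeplete.errors import MetricError

CG_STRATA_PERCENT = ((0.0, 1.0), (1.0, 2.0), (2.0, 4.0), (4.0, 10.0), (10.0, 100.0))


@dataclass
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_tsv(self, path: os.PathLike | str) -> None:
        with open(path, "w") as handle:
            handle.write("metric\tvalue\n")
            for name in ("accuracy", "sensitivity", "specificity", "tp", "fp", "tn", "fn"):
                handle.write(f"{name}\t{getattr(self, name)}\n")


def confusion_metrics(predictions: Sequence[int], truth: Sequence[int]) -> MetricReport:
    """Confusion counts and accuracy/sensitivity/specificity (host positive).

    A single-class truth leaves the undefined metric as NaN with a warning.
    """
    if len(predictions) != len(truth):
        raise MetricError("predictions and truth differ in length")
    if len(truth) == 0:
        raise MetricError("empty label collections")
    tp = fp = tn = fn = 0
    for pred, true in zip(predictions, truth):
        if true == 1:
            tp += pred == 1
            fn += pred == 0
        else:
            tn += pred == 0
            fp += pred == 1
    accuracy = (tp + tn) / len(truth)
    if tp + fn == 0:
        warnings.warn("no host reads in truth; sensitivity undefined")
        sensitivity = math.nan
    else:
        sensitivity = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no microbe reads in truth; specificity undefined")
        specificity = math.nan
    else:
        specificity = tn / (tn + fp)
    return MetricReport(accuracy, sensitivity, specificity, tp, fp, tn, fn)


def cg_fraction(bases: str) -> float:
    """Overlapping 'CG' dimer count over (length - 1)."""
    if len(bases) < 2:
        raise MetricError("cg_fraction undefined for sequences shorter than 2 bp")
    return bases.upper().count("CG") / (len(bases) - 1)


def naive_cg_classifier(bases: str, cg_threshold: float) -> int:
    """0 (microbe) iff the CG dimer fraction is >= the threshold, else 1 (host)."""
    return 0 if cg_fraction(bases) >= cg_threshold else 1


def calibrate_cg_threshold(reads: Sequence[str], labels: Sequence[int]) -> float:
    """Youden-optimal CG threshold for the naive classifier.

    Mirrors the CNN's calibration: scan the observed CG fractions (plus the
    extremes); host is the *low*-CG class so the decision is inverted before
    the scan.
    """
    fractions = [cg_fraction(b) for b in reads]
    # classify() labels host when score > threshold; host has low CG, so
    # score by -cg and flip the sign of the returned cut.
    thresh, _ = best_youden_threshold([1.0 - f for f in fractions], labels)
    return 1.0 - thresh


def stratify_by_cg(reads: Sequence[str]) -> List[List[int]]:
    """Partition read indices into the five CG-percentage strata.

    Strata are left-closed/right-open on [0,1), [1,2), [2,4), [4,10) percent
    with the final stratum [10, 100] closed on the right.
    """
    strata: List[List[int]] = [[] for _ in CG_STRATA_PERCENT]
    for idx, bases in enumerate(reads):
        pct = cg_fraction(bases) * 100.0
        for s, (lo, hi) in enumerate(CG_STRATA_PERCENT):
            if lo <= pct < hi or (s == len(CG_STRATA_PERCENT) - 1 and pct <= hi):
                strata[s].append(idx)
                break
    return strata


def _kmer_set(reads: Iterable[str], k: int) -> Set[str]:
    kmers: Set[str] = set()
    for bases in reads:
        upper = bases.upper()
        for i in range(len(upper) - k + 1):
            kmers.add(upper[i : i + k])
    return kmers


def kmer_uniqueness(host_reads: Sequence[str], microbe_reads: Sequence[str], k: int) -> float:
    """Fraction of distinct host k-mers absent from the microbe k-mer set."""
    host_kmers = _kmer_set(host_reads, k)
    if not host_kmers:
        raise MetricError(f"no host k-mers of length {k}")
    microbe_kmers = _kmer_set(microbe_reads, k)
    return len(host_kmers - microbe_kmers) / len(host_kmers)
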