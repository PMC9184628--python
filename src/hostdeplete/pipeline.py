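"""End-to-end host depletion: passes -> batches -> forward -> thresholds -> files.

The input file is streamed once to collect (id, length) pairs for pass
planning, once per pass to stage the truncated sequences that pass needs,
and a final time to emit the untruncated microbial reads.  Output files are
written to temporary names and renamed on success so interrupted runs leave
no truncated ``mlpaths`` / ``mlprobs`` behind.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from hostdeplete.binning import BinningConfig, plan_batches, plan_passes
from hostdeplete.calibration import ThresholdTable, classify, select_threshold
from hostdeplete.errors import UsageError
from hostdeplete.model import ConvNet, load_model
from hostdeplete.sequence_io import (
    ClassificationRecord,
    encode_batch,
    read_sequences,
    write_microbial_reads,
    write_predictions,
)

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    input_path: Path
    format: str
    output_folder: Path
    model_path: Path
    threshold_path: Optional[Path] = None
    binning: BinningConfig = field(default_factory=BinningConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.input_path = Path(self.input_path)
        self.output_folder = Path(self.output_folder)
        self.model_path = Path(self.model_path)
        if self.format not in ("fasta", "fastq"):
            raise UsageError(f"format must be fasta or fastq, got {self.format!r}")


@dataclass
class RunSummary:
    n_input: int
    n_rejected: int
    n_host: int
    n_microbe: int
    n_passes: int
    elapsed_seconds: float
    predictions_path: Path
    microbial_path: Path


def _classify_pass(
    model: ConvNet,
    manifest: RunManifest,
    bins,
    lengths: Dict[str, int],
    table: ThresholdTable,
    records: Dict[str, ClassificationRecord],
) -> None:
    wanted: Dict[str, int] = {}
    for b in bins:
        for rid in b.member_ids:
            wanted[rid] = b.truncation_length
    staged: Dict[str, str] = {}
    for read in read_sequences(manifest.input_path, manifest.format):
        if read.id in wanted and read.id not in staged:
            staged[read.id] = read.bases[: wanted[read.id]]
    for b in bins:
        for batch_ids in plan_batches(b, manifest.binning):
            batch = encode_batch([staged[rid] for rid in batch_ids], b.truncation_length)
            probs = model.forward(batch)
            for rid, prob in zip(batch_ids, probs):
                orig_len = lengths[rid]
                threshold = select_threshold(orig_len, table)
                records[rid] = ClassificationRecord(
                    id=rid,
                    probability=float(prob),
                    label=classify(float(prob), threshold),
                    length=orig_len,
                )


def run_host_depletion(manifest: RunManifest, model: Optional[ConvNet] = None) -> RunSummary:
    """Classify every read of the input file and write the two output files."""
    start_time = time.time()
    out = manifest.output_folder
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("hostdeplete")
    root.addHandler(log_handler)
    root.setLevel(manifest.log_level)
    try:
        logger.info("run seed=%d input=%s format=%s", manifest.seed, manifest.input_path, manifest.format)
        if model is None:
            model = load_model(manifest.model_path)
        table = (
            ThresholdTable.from_file(manifest.threshold_path)
            if manifest.threshold_path
            else ThresholdTable()
        )

        order: List[str] = []
        lengths: Dict[str, int] = {}
        n_input = 0
        for read in read_sequences(manifest.input_path, manifest.format):
            n_input += 1
            if read.id in lengths:
                continue
            order.append(read.id)
            lengths[read.id] = read.length

        passes = plan_passes(((rid, lengths[rid]) for rid in order), manifest.binning)
        accepted = {rid for p in passes for b in p for rid in b.member_ids}
        n_rejected = len(order) - len(accepted)
        logger.info("%d read(s), %d accepted, %d rejected (< %d bp), %d pass(es)",
                    n_input, len(accepted), n_rejected, manifest.binning.inc1, len(passes))

        records: Dict[str, ClassificationRecord] = {}
        for i, pass_bins in enumerate(passes, 1):
            logger.info("pass %d/%d: %d bin(s)", i, len(passes), len(pass_bins))
            _classify_pass(model, manifest, pass_bins, lengths, table, records)

        ordered_records = [records[rid] for rid in order if rid in records]
        pred_path = out / "mlprobs.txt"
        tmp_pred = out / ".mlprobs.txt.tmp"
        write_predictions(ordered_records, tmp_pred)
        os.replace(tmp_pred, pred_path)

        micro_path = out / f"mlpaths.{manifest.format}"
        tmp_micro = out / f".mlpaths.{manifest.format}.tmp"
        accepted_reads = (
            r for r in read_sequences(manifest.input_path, manifest.format) if r.id in records
        )
        write_microbial_reads(accepted_reads, records, manifest.format, tmp_micro)
        os.replace(tmp_micro, micro_path)

        n_host = sum(rec.label == 1 for rec in ordered_records)
        n_microbe = len(ordered_records) - n_host
        elapsed = time.time() - start_time
        logger.info("done: %d host, %d microbe, %.2f s", n_host, n_microbe, elapsed)
        return RunSummary(
            n_input=n_input,
            n_rejected=n_rejected,
            n_host=n_host,
            n_microbe=n_microbe,
            n_passes=len(passes),
            elapsed_seconds=elapsed,
            predictions_path=pred_path,
            microbial_path=micro_path,
        )
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
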