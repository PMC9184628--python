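# hostdeplete

Index-free host depletion for long sequencing reads. A variable-length
convolutional classifier — conv/ReLU/average-pool stages topped by global
average pooling and a single logistic unit — scores each read with a host
probability, so no reference genome or index database is needed. Reads are
grouped into length bins and processed in memory-bounded passes, decisions
use length-dependent probability thresholds, and a synthetic read generator
(host-like reads with suppressed CG dinucleotides vs. microbe-like reads
without) makes the whole system trainable and testable offline.

The neural network (forward pass, backprop, Adam, the double-backprop needed
for input-gradient regularization, and DeepLift-style rescale attribution)
is implemented in pure NumPy; no deep-learning framework is required.

## CLI

Classify a read set (outputs `mlprobs.txt` — id/label/length TSV — and
`mlpaths.fastq` with the reads classified as microbial, plus `run.log`):

```sh
host-deplete generate --n 2000 --host-fraction 0.5 --seed 7 -o data/
host-deplete train --reads data/reads.fastq --truth data/truth.tsv \
    --lengths 100,1000 --max-epochs 5 -o model.npz
host-deplete calibrate --model model.npz --reads data/reads.fastq \
    --truth data/truth.tsv --lengths 100,1000 -o thresholds.tsv
host-deplete run -i data/reads.fastq -t fastq -o out/ \
    --model model.npz --thresholds thresholds.tsv
host-deplete evaluate --pred out/mlprobs.txt --truth data/truth.tsv
host-deplete attribute --model model.npz -i data/reads.fastq -o attr.tsv
```

Binning constants (`seq_cutoff`, `inc1`, `inc2`, `max_len`, `lim`,
`batch_max_len`) can be overridden with a YAML file passed to
`run --config`.

## Layout

| module | role |
| --- | --- |
| `hostdeplete.sequence_io` | FASTA/FASTQ I/O, one-hot encoding, output files |
| `hostdeplete.binning` | length bins, batch plans, memory-bounded passes |
| `hostdeplete.model` | the NumPy CNN, gradients, checkpointing |
| `hostdeplete.calibration` | per-length Youden-J thresholds |
| `hostdeplete.training` | BCE + L2 + input-gradient penalty, Adam, early stopping |
| `hostdeplete.synthetic_data` | Markov-chain read generator with Nanopore-like noise |
| `hostdeplete.evaluation` | confusion metrics, CG baseline/strata, k-mer uniqueness |
| `hostdeplete.attribution` | reference-based per-nucleotide contribution scores |
| `hostdeplete.pipeline` / `hostdeplete.cli` | end-to-end orchestration and CLI |
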